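"""JSON round trip for cell pools (cell id, age, SRM parameters, scaling,
firing rate)."""

from __future__ import annotations

import json

from .srm import SRMParams
from .stimulus import ScalingSpec
from .population import PoolCell, CellPool


def pool_to_json(pool: CellPool) -> str:
    cells = []
    for c in pool.cells:
        cells.append({
            "cell_id": c.cell_id,
            "age": c.age,
            "params": json.loads(c.params.to_json()),
            "scaling": {"mu": c.scaling.mu, "sigma": c.scaling.sigma},
            "rate_hz": c.rate_hz,
        })
    return json.dumps({"cells": cells}, indent=1)


def pool_from_json(path_or_text) -> CellPool:
    text = path_or_text
    if "\n" not in str(path_or_text) and str(path_or_text).endswith(".json"):
        with open(path_or_text) as fh:
            text = fh.read()
    d = json.loads(text)
    cells = []
    for c in d["cells"]:
        cells.append(PoolCell(
            cell_id=c["cell_id"], age=c["age"],
            params=SRMParams.from_json(json.dumps(c["params"])),
            scaling=ScalingSpec(**c["scaling"]),
            rate_hz=c["rate_hz"]))
    return CellPool(cells)
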