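"""Small shared helpers."""

from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (spreadsheet convention).

    Python's built-in ``round`` is banker's rounding; percentage tables
    here follow the half-up convention instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def load_data_json(name: str) -> dict:
    """Load a JSON resource bundled under ``memidr/data``."""
    with resources.files("memidr.data").joinpath(name).open() as fh:
        return json.load(fh)
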