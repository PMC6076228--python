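"""Small shared helpers: rounding, atomic file writes, chromosome labels."""

from __future__ import annotations

import os
import tempfile
from decimal import Decimal, ROUND_HALF_UP


class MendiagError(Exception):
    """Base class for data/format errors raised by this package."""


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (spreadsheet-style), not banker's."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def ratio_pct(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """Exact percentage numerator/denominator*100, rounded half-up."""
    q = Decimal(1).scaleb(-ndigits)
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def norm_chrom(chrom: str) -> str:
    """Normalize a chromosome label by stripping a leading 'chr'."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write via a temp file in the target directory, then rename."""
    path = os.fspath(path)
    d = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp_", suffix=os.path.basename(path))
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
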