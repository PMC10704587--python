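"""The instrument calibration function (ICF).

The ICF folds quadrupole mass discrimination and differential ion diffusion
into a single empirical correction factor per m/z, anchored at the product
ions of a certified multicomponent gas standard during the automated
performance check.  By definition the ICF is exactly 1 on m/z 28-32 (and at
-32): the reaction-time determination assumes equal transmission there, and
all other values are expressed relative to that plateau.

Between anchors the curve is piecewise-linear in (m/z, ICF); beyond the
highest anchor it is carried by the stored extrapolated endpoint at |m/z|
400, and below the lowest anchor it extends flat down to |m/z| 10 (the
instrument's mass range).
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, field_validator

__all__ = ["ICFCurve", "icf_lookup", "MZ_MIN", "MZ_MAX"]

MZ_MIN = 10
MZ_MAX = 400

#: positive-polarity plateau on which ICF == 1 by definition
PLATEAU = (28, 32)


class ICFCurve(BaseModel):
    """Piecewise-linear ICF anchored at signed m/z values."""

    anchors: dict[int, float]

    @field_validator("anchors")
    @classmethod
    def _positive(cls, v: dict[int, float]) -> dict[int, float]:
        if not v:
            raise ValueError("ICF curve needs at least one anchor")
        for mz, val in v.items():
            if val <= 0:
                raise ValueError(f"ICF anchor at m/z {mz} must be > 0, got {val}")
            if not (MZ_MIN <= abs(mz) <= MZ_MAX):
                raise ValueError(f"ICF anchor m/z {mz} outside |m/z| 10..400")
        for mz in range(PLATEAU[0], PLATEAU[1] + 1):
            if mz in v and abs(v[mz] - 1.0) > 1e-12:
                raise ValueError(f"ICF at m/z {mz} must be 1 by definition")
        if -32 in v and abs(v[-32] - 1.0) > 1e-12:
            raise ValueError("ICF at m/z -32 must be 1 by definition")
        return v

    def _side(self, positive: bool) -> tuple[np.ndarray, np.ndarray]:
        items = sorted((abs(mz), val) for mz, val in self.anchors.items()
                       if (mz > 0) == positive)
        if not items:
            raise ValueError(
                f"ICF curve has no {'positive' if positive else 'negative'} "
                "anchors")
        mags = np.array([m for m, _ in items], dtype=float)
        vals = np.array([v for _, v in items], dtype=float)
        return mags, vals

    def lookup(self, mz: float) -> float:
        """ICF value at a signed m/z (piecewise-linear; exact at anchors)."""
        if mz == 0 or not (MZ_MIN <= abs(mz) <= MZ_MAX):
            raise ValueError(f"m/z {mz} outside instrument range |m/z| 10..400")
        if mz > 0 and PLATEAU[0] <= mz <= PLATEAU[1]:
            return 1.0
        if mz == -32:
            return 1.0
        mags, vals = self._side(mz > 0)
        # flat extension below the lowest / above the highest anchor
        return float(np.interp(abs(mz), mags, vals))

    def anchor_mzs(self, positive: bool | None = None) -> list[int]:
        mzs = sorted(self.anchors, key=abs)
        if positive is None:
            return mzs
        return [m for m in mzs if (m > 0) == positive]


def icf_lookup(curve: ICFCurve, mz: float) -> float:
    """Functional form of :meth:`ICFCurve.lookup`."""
    return curve.lookup(mz)


def flat_icf(value: float = 1.0) -> ICFCurve:
    """A constant ICF curve (useful as an identity-transmission truth)."""
    return ICFCurve(anchors={MZ_MIN: value, MZ_MAX: value,
                             -MZ_MIN: value, -MZ_MAX: value}
                    if value == 1.0 else
                    {MZ_MIN: value, 27: value, 33: value, MZ_MAX: value,
                     -MZ_MIN: value, -27: value, -33: value, -MZ_MAX: value})
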