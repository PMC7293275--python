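"""WES-versus-genotyping-array concordance via discrepancy allowance.

A site shared by both platforms is concordant at allowance ``a`` when the
absolute difference between the sequencing VAF and the array allele frequency
(0, 0.5 or 1) is at most ``a`` (boundary inclusive). The overlap rate pools
shared sites across samples; a per-sample breakdown is also reported by the
sweep. Sites absent from either platform are excluded from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import KEY


class NoSharedSitesError(ValueError):
    """Raised when the two platforms share no sites."""


def _shared(wes: pd.DataFrame, array: pd.DataFrame) -> pd.DataFrame:
    merged = wes[KEY + ["vaf"]].merge(array[KEY + ["array_af"]], on=KEY, how="inner")
    if merged.empty:
        raise NoSharedSitesError("no sites shared between WES and array tables")
    return merged


def overlap_rate(wes: pd.DataFrame, array: pd.DataFrame, allowance: float) -> float:
    """Fraction of shared sites with |VAF_wes - AF_array| <= allowance."""
    shared = _shared(wes, array)
    disc = (shared["vaf"] - shared["array_af"]).abs()
    return float((disc <= allowance).mean())


@dataclass
class ConcordanceCurve:
    allowances: np.ndarray
    rates: np.ndarray
    n_shared: int
    per_sample: pd.DataFrame    # samples x allowances overlap rates

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"allowance": self.allowances, "overlap_rate": self.rates})


def allowance_sweep(wes: pd.DataFrame, array: pd.DataFrame, grid) -> ConcordanceCurve:
    """Overlap rate at each allowance of an ascending grid.

    The resulting curve is non-decreasing in the allowance and reaches 1.0 at
    any allowance >= 1.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size and not (np.diff(grid) >= 0).all():
        raise ValueError("allowance grid must be sorted ascending")
    shared = _shared(wes, array)
    disc = (shared["vaf"] - shared["array_af"]).abs().to_numpy()
    rates = np.array([(disc <= a).mean() for a in grid])
    per = shared.assign(disc=disc).groupby("sample")["disc"]
    per_sample = pd.DataFrame(
        {a: per.apply(lambda d, a=a: (d <= a).mean()) for a in grid}
    )
    return ConcordanceCurve(grid, rates, n_shared=len(shared), per_sample=per_sample)
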