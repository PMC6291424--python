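"""Expression-matrix handling and small quantification statistics.

The matrix type consumes already-normalized values (e.g. RMA on log2
scale) plus per-sample detection calls (e.g. MAS5 present/absent);
normalization itself is upstream of this package.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import GeneSet, InputError

ARM_ANTAGOMIR = "antagomir_31"
ARM_CONTROL = "antagomir_scr"
TIMEPOINTS = (36, 48, 72)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with arm/timepoint metadata.

    ``values``: DataFrame indexed by gene id, one column per sample.
    ``meta``: DataFrame indexed by sample with columns ``arm``
    (``antagomir_31`` / ``antagomir_scr``), ``timepoint`` (hours, int) and
    ``replicate``.
    ``presence``: boolean DataFrame of detection calls, same shape as
    ``values``; defaults to all-present.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    presence: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        missing = {"arm", "timepoint"} - set(self.meta.columns)
        if missing:
            raise InputError(f"sample sheet lacks columns: {sorted(missing)}")
        if list(self.values.columns) != list(self.meta.index):
            if set(self.values.columns) != set(self.meta.index):
                raise InputError("sample sheet does not match matrix columns")
            self.meta = self.meta.loc[list(self.values.columns)]
        if self.presence is None:
            self.presence = pd.DataFrame(
                True, index=self.values.index, columns=self.values.columns
            )
        if self.presence.shape != self.values.shape:
            raise InputError("presence calls must share the matrix dimensions")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def arm_labels(self) -> pd.Series:
        return self.meta["arm"]

    def subset_timepoint(self, timepoint: int) -> "ExpressionMatrix":
        keep = self.meta.index[self.meta["timepoint"] == timepoint]
        if len(keep) == 0:
            raise InputError(f"no samples at timepoint {timepoint}")
        return ExpressionMatrix(
            self.values[keep], self.meta.loc[keep], self.presence[keep]
        )

    def subset_genes(self, genes) -> "ExpressionMatrix":
        idx = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(
            self.values.loc[idx], self.meta, self.presence.loc[idx]
        )

    def timepoints(self) -> list[int]:
        return sorted(self.meta["timepoint"].unique())


def presence_filter(
    m: ExpressionMatrix,
    fraction: float = 0.5,
    per_timepoint: bool = False,
    set_name: str = "expressed",
) -> GeneSet:
    """Genes detected in at least ``fraction`` of either arm's samples.

    A gene is kept when it is called present in >= ``fraction`` of the
    antagomir samples OR >= ``fraction`` of the scrambled-control samples.
    By default samples are pooled across timepoints within an arm; with
    ``per_timepoint`` the rule is applied separately per timepoint and a
    gene is kept if it passes at any timepoint.
    """
    if not 0 <= fraction <= 1:
        raise InputError("fraction must lie in [0, 1]")
    arms = m.meta["arm"]
    for arm in (ARM_ANTAGOMIR, ARM_CONTROL):
        if (arms == arm).sum() == 0:
            raise InputError(f"arm {arm!r} has no samples")

    def _passes(cols) -> pd.Series:
        sub = m.presence[cols]
        return sub.mean(axis=1) >= fraction

    keep = pd.Series(False, index=m.values.index)
    if per_timepoint:
        for tp in m.timepoints():
            for arm in (ARM_ANTAGOMIR, ARM_CONTROL):
                cols = m.meta.index[(arms == arm) & (m.meta["timepoint"] == tp)]
                if len(cols):
                    keep |= _passes(cols)
    else:
        for arm in (ARM_ANTAGOMIR, ARM_CONTROL):
            cols = m.meta.index[arms == arm]
            keep |= _passes(cols)
    return GeneSet(set_name, keep.index[keep])


def delta_ct(target_ct: float, reference_ct: float) -> float:
    """Relative expression by the change-in-threshold method, 2^-(dCT).

    dCT = target CT - reference CT; one extra cycle halves the estimate.
    """
    if not (np.isfinite(target_ct) and np.isfinite(reference_ct)):
        raise InputError("CT values must be finite")
    return float(2.0 ** (-(target_ct - reference_ct)))


def fold_change_vs_control(
    treated, control, mode: str = "arithmetic"
) -> float:
    """Mean relative expression of treated samples over the control mean."""
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.size == 0 or control.size == 0:
        raise InputError("fold change needs non-empty samples")
    if mode == "arithmetic":
        c = control.mean()
        if c <= 0:
            raise InputError("control mean must be > 0")
        return float(treated.mean() / c)
    if mode == "geometric":
        if np.any(treated <= 0) or np.any(control <= 0):
            raise InputError("geometric mode needs strictly positive values")
        return float(np.exp(np.log(treated).mean() - np.log(control).mean()))
    raise InputError(f"unknown mode {mode!r}")


def mann_whitney(a, b, mode: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U test for unpaired data, two-sided.

    ``auto`` uses the exact null distribution when both samples have at
    most 8 observations and there are no ties, otherwise the tie-corrected
    normal approximation. Returns ``(U, p)`` with U for the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("Mann-Whitney needs non-empty samples")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    elif mode == "exact":
        method = "exact"
    elif mode == "normal_approx":
        method = "asymptotic"
    else:
        raise InputError(f"unknown mode {mode!r}")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
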