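"""Within-subject statistics: one-factor repeated-measures ANOVA and
unadjusted post hoc paired comparisons.

Each analysis cell is a participants x stimuli matrix of baseline changes
(EX means) for one group, index and exposure window. The ANOVA partitions

    SS_total = SS_subjects + SS_conditions + SS_error,

with F = MS_conditions / MS_error on (k-1, (n-1)(k-1)) degrees of freedom.
The p-value is uncorrected for sphericity, mirroring the study design; a
Greenhouse-Geisser corrected p is reported alongside for transparency.
Post hoc comparisons are two-sided paired t tests over all k(k-1)/2 pairs
with no adjustment of p-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

log = logging.getLogger(__name__)

SIGNIFICANCE_LEVELS = (0.05, 0.01, 0.001)


@dataclass(frozen=True)
class WithinSubjectMatrix:
    """Complete-case participants x conditions matrix for one analysis cell."""

    data: np.ndarray  # shape (n_subjects, k_conditions)
    conditions: tuple[str, ...]
    participants: tuple[str, ...]
    index_name: str = ""
    group: str = ""
    window: str = ""

    @classmethod
    def from_rows(
        cls,
        rows: dict[str, dict[str, float]],
        conditions: tuple[str, ...],
        **meta: str,
    ) -> "WithinSubjectMatrix":
        """Build from per-participant condition->value maps, dropping
        participants with any missing/undefined cell (listwise deletion)."""
        kept, dropped = [], []
        for pid in sorted(rows):
            vals = [rows[pid].get(c, float("nan")) for c in conditions]
            if np.all(np.isfinite(vals)):
                kept.append((pid, vals))
            else:
                dropped.append(pid)
        if dropped:
            log.info("listwise deletion dropped %d participant(s): %s", len(dropped), dropped)
        data = np.array([v for _, v in kept], dtype=float).reshape(len(kept), len(conditions))
        return cls(
            data=data,
            conditions=tuple(conditions),
            participants=tuple(p for p, _ in kept),
            **meta,
        )


@dataclass(frozen=True)
class ANOVAResult:
    F: float
    df_num: int
    df_den: int
    p: float
    p_gg: float
    eps_gg: float
    ss_conditions: float
    ss_subjects: float
    ss_error: float


@dataclass(frozen=True)
class PairwiseComparison:
    stim_a: str
    stim_b: str
    t: float
    df: int
    p: float
    mean_diff: float

    @property
    def significance(self) -> str:
        """Star notation at the conventional 0.05 / 0.01 / 0.001 levels."""
        if not np.isfinite(self.p):
            return ""
        return "*" * sum(self.p < a for a in SIGNIFICANCE_LEVELS)


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity estimate from the condition covariance."""
    k = data.shape[1]
    s = np.cov(data, rowvar=False, ddof=1)
    # Double-center the covariance matrix.
    row = s.mean(axis=0, keepdims=True)
    dc = s - row - row.T + s.mean()
    num = np.trace(dc) ** 2
    den = (k - 1) * np.sum(dc**2)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def rm_anova(m: WithinSubjectMatrix) -> ANOVAResult:
    """One-factor repeated-measures ANOVA on a complete-case matrix."""
    x = m.data
    n, k = x.shape
    if n < 3:
        raise ValueError("insufficient complete cases: need at least 3 participants")
    if k < 2:
        raise ValueError("need at least 2 conditions")
    grand = x.mean()
    ss_subj = k * float(((x.mean(axis=1) - grand) ** 2).sum())
    ss_cond = n * float(((x.mean(axis=0) - grand) ** 2).sum())
    ss_tot = float(((x - grand) ** 2).sum())
    ss_err = max(ss_tot - ss_subj - ss_cond, 0.0)
    df_num, df_den = k - 1, (n - 1) * (k - 1)
    ms_cond = ss_cond / df_num
    ms_err = ss_err / df_den
    eps = _gg_epsilon(x)
    if ms_err == 0.0:
        if ss_cond == 0.0:
            # All cells identical up to subject offsets: no condition effect.
            return ANOVAResult(0.0, df_num, df_den, 1.0, 1.0, eps, ss_cond, ss_subj, ss_err)
        warnings.warn("zero error variance; p reported as 0", stacklevel=2)
        return ANOVAResult(float("inf"), df_num, df_den, 0.0, 0.0, eps, ss_cond, ss_subj, ss_err)
    f = ms_cond / ms_err
    p = float(sps.f.sf(f, df_num, df_den))
    p_gg = float(sps.f.sf(f, eps * df_num, eps * df_den))
    return ANOVAResult(float(f), df_num, df_den, p, p_gg, eps, ss_cond, ss_subj, ss_err)


def posthoc_pairwise(m: WithinSubjectMatrix) -> list[PairwiseComparison]:
    """All k(k-1)/2 two-sided paired t tests, p-values unadjusted."""
    x = m.data
    n, k = x.shape
    if n < 3:
        raise ValueError("insufficient complete cases: need at least 3 participants")
    out = []
    for ia, ib in combinations(range(k), 2):
        d = x[:, ia] - x[:, ib]
        mean_diff = float(d.mean())
        sd = float(d.std(ddof=1))
        if sd == 0.0:
            if mean_diff == 0.0:
                t = float("nan")
                p = float("nan")
                log.info("degenerate pair %s vs %s: identical columns", m.conditions[ia], m.conditions[ib])
            else:
                warnings.warn("zero-variance difference vector; p reported as 0", stacklevel=2)
                t = float(np.inf * np.sign(mean_diff))
                p = 0.0
        else:
            t = mean_diff / (sd / np.sqrt(n))
            p = float(2.0 * sps.t.sf(abs(t), n - 1))
        out.append(
            PairwiseComparison(m.conditions[ia], m.conditions[ib], float(t), n - 1, p, mean_diff)
        )
    return out
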