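"""Group-level spectral comparisons between oculomotor-sign cohorts.

The clinical question is whether the relative spectral power of the pursuit
signal separates subjects with saccadic pursuit from those without oculomotor
abnormalities.  Comparisons use the Mann-Whitney U test with the rank-biserial
correlation ``r = 2U/(n1 n2) - 1`` as effect size; p values on the 0.05 Hz
frequency sweep are reported raw, without multiple-testing correction.

Group selectors follow the clinical shorthand: ``SP+`` (saccadic pursuit
present), ``SP-`` (absent), ``SP*`` (the only sign), ``DS*`` (dysmetric
saccades the only sign), ``TYP`` (no oculomotor signs and oculomotor score
0).  Groups may overlap.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .conceft import default_freq_grid
from .errors import InvalidParameterError

__all__ = [
    "SubjectRecord",
    "GroupComparison",
    "GROUP_SELECTORS",
    "mann_whitney_u",
    "rank_biserial",
    "frequency_sweep",
    "band_contrast",
]

SIGN_NAMES = ("saccadic_pursuit", "nystagmus", "dysmetric_saccades", "slowed_saccades", "gaze_holding")


@dataclass
class SubjectRecord:
    """One subject's metadata, features and spectral summaries."""

    subject_id: str
    diagnosis: str = "control"  # ataxia | parkinson | control
    signs: dict = field(default_factory=dict)  # sign name -> bool
    bars_oculomotor: float = 0.0
    features: dict = field(default_factory=dict)  # trial_id -> ConceFTFeatures
    band_fraction: float | None = None  # 1.5-2.5 Hz relative power
    relative_power: np.ndarray | None = None  # per-grid-bin relative power
    freq_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.bars_oculomotor not in (0.0, 0.5, 1.0, 1.5, 2.0):
            raise InvalidParameterError(
                f"bars_oculomotor must be a half-point step in [0, 2], got {self.bars_oculomotor}"
            )

    def has_sign(self, name: str) -> bool:
        return bool(self.signs.get(name, False))

    @property
    def any_sign(self) -> bool:
        return any(self.signs.get(s, False) for s in SIGN_NAMES)


def _only_sign(rec: SubjectRecord, name: str) -> bool:
    return rec.has_sign(name) and not any(
        rec.signs.get(s, False) for s in SIGN_NAMES if s != name
    )


GROUP_SELECTORS = {
    "SP+": lambda r: r.has_sign("saccadic_pursuit"),
    "SP-": lambda r: not r.has_sign("saccadic_pursuit"),
    "SP*": lambda r: _only_sign(r, "saccadic_pursuit"),
    "DS*": lambda r: _only_sign(r, "dysmetric_saccades"),
    "N*": lambda r: _only_sign(r, "nystagmus"),
    "TYP": lambda r: (not r.any_sign) and r.bars_oculomotor == 0.0,
}


@dataclass
class GroupComparison:
    """Mann-Whitney U contrast between two groups."""

    u_statistic: float
    p_value: float
    effect_size: float
    n1: int
    n2: int


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U = #{a_i > b_j} + 0.5 #{a_i = b_j} via rank sums (tie-aware)."""
    n1 = len(a)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_u(a, b, exact_limit: int = 12) -> tuple[float, float]:
    """Mann-Whitney U statistic and two-sided p value.

    For ``n1 + n2 <= exact_limit`` the p value is computed by exhaustive
    enumeration of all group assignments of the pooled sample (a permutation
    test, valid under ties); larger samples use the tie-corrected normal
    approximation with continuity correction.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise InvalidParameterError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    u = _u_statistic(a, b)

    if n1 + n2 <= exact_limit:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        mu = n1 * n2 / 2.0
        obs_dev = abs(u - mu)
        offset = n1 * (n1 + 1) / 2.0
        count = 0
        total = 0
        for comb in itertools.combinations(range(n1 + n2), n1):
            u_p = ranks[list(comb)].sum() - offset
            if abs(u_p - mu) >= obs_dev - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return u, min(1.0, float(p))


def rank_biserial(a, b) -> float:
    """Rank-biserial correlation, positive when ``a`` stochastically dominates ``b``."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise InvalidParameterError("both groups must be non-empty")
    u = _u_statistic(a, b)
    return float(2.0 * u / (len(a) * len(b)) - 1.0)


def compare_groups(a, b) -> GroupComparison:
    u, p = mann_whitney_u(a, b)
    return GroupComparison(u, p, rank_biserial(a, b), len(a), len(b))


def _select(subjects, selector):
    if callable(selector):
        return [s for s in subjects if selector(s)]
    try:
        fn = GROUP_SELECTORS[selector]
    except KeyError:
        raise InvalidParameterError(f"unknown group selector {selector!r}") from None
    return [s for s in subjects if fn(s)]


def frequency_sweep(
    subjects: list[SubjectRecord],
    group_a_selector,
    group_b_selector,
    increment_hz: float = 0.05,
) -> pd.DataFrame:
    """Per-frequency group contrast of relative power across 0.1-8 Hz.

    Each subject must carry a ``relative_power`` spectrum on a common grid;
    at each grid frequency the two groups' relative power is compared with
    the Mann-Whitney U test.  Returns a tidy frame with columns
    ``freq_hz, u, p, effect_size, n1, n2``.
    """
    ga = _select(subjects, group_a_selector)
    gb = _select(subjects, group_b_selector)
    if not ga or not gb:
        raise InvalidParameterError("a group selector yielded no subjects")
    grid = None
    for s in ga + gb:
        if s.relative_power is None:
            raise InvalidParameterError(f"subject {s.subject_id} has no spectrum")
        g = s.freq_grid if s.freq_grid is not None else default_freq_grid(step=increment_hz)
        if grid is None:
            grid = np.asarray(g, float)
        elif len(g) != len(grid) or not np.allclose(g, grid):
            raise InvalidParameterError("subjects carry spectra on different grids")
    A = np.stack([s.relative_power for s in ga])
    B = np.stack([s.relative_power for s in gb])
    rows = []
    for j, f in enumerate(grid):
        u, p = mann_whitney_u(A[:, j], B[:, j])
        rows.append(
            {
                "freq_hz": float(f),
                "u": u,
                "p": p,
                "effect_size": rank_biserial(A[:, j], B[:, j]),
                "n1": len(ga),
                "n2": len(gb),
            }
        )
    return pd.DataFrame(rows)


def _fraction(rec: SubjectRecord, lo: float, hi: float) -> float:
    """Subject's band-power fraction, from the stored spectrum when possible."""
    if rec.relative_power is not None:
        grid = rec.freq_grid if rec.freq_grid is not None else default_freq_grid()
        grid = np.asarray(grid, float)
        sel = (grid >= lo - 1e-9) & (grid < hi - 1e-9)
        if hi >= grid[-1] - 1e-9:
            sel = (grid >= lo - 1e-9) & (grid <= hi + 1e-9)
        return float(rec.relative_power[sel].sum() / rec.relative_power.sum())
    if rec.band_fraction is not None and math.isclose(lo, 1.5) and math.isclose(hi, 2.5):
        return rec.band_fraction
    raise InvalidParameterError(f"subject {rec.subject_id} has no spectral summary")


def band_contrast(
    subjects: list[SubjectRecord],
    groups: list,
    lo: float = 1.5,
    hi: float = 2.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Band-power fractions per group plus all pairwise Mann-Whitney contrasts.

    ``groups`` is a list of selector names (``SP+`` ...) or callables; groups
    may overlap.  Returns ``(fractions, comparisons)`` data frames.
    """
    frac_rows = []
    members: dict[str, list[float]] = {}
    for g in groups:
        name = g if isinstance(g, str) else getattr(g, "__name__", "group")
        sel = _select(subjects, g)
        if not sel:
            raise InvalidParameterError(f"group {name!r} is empty")
        vals = [_fraction(s, lo, hi) for s in sel]
        members[name] = vals
        frac_rows.extend(
            {"group": name, "subject_id": s.subject_id, "band_fraction": v}
            for s, v in zip(sel, vals)
        )
    comp_rows = []
    for (na, va), (nb, vb) in itertools.combinations(members.items(), 2):
        c = compare_groups(va, vb)
        comp_rows.append(
            {
                "group_a": na,
                "group_b": nb,
                "n1": c.n1,
                "n2": c.n2,
                "u": c.u_statistic,
                "p": c.p_value,
                "effect_size": c.effect_size,
            }
        )
    return pd.DataFrame(frac_rows), pd.DataFrame(comp_rows)


__all__.append("compare_groups")
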