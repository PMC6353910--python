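"""Statistical comparisons for particle densities and ring distributions.

Density comparisons across strains follow the usual workflow for small
per-cell samples: Shapiro-Wilk normality checks per group, then a one-way
ANOVA; when any normality check fails, a Kruskal-Wallis test is reported
alongside with a warning flag.

The distribution of particles over the three NPC rings is compared pairwise.
Two procedures are offered for a ring pair (A, B): a Mann-Whitney U test on
the binary per-particle ring indicators (kept for comparability with
published analyses, although U on binary data reduces to a proportion
comparison), and the default label-permutation test, whose null — each of
the n_A + n_B particles lands in either ring with probability 1/2 — is
evaluated exactly through the binomial law, or by Monte Carlo when asked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupedDensities",
    "RingCounts",
    "DensityAnovaResult",
    "density_anova",
    "ring_distribution_test",
    "ring_proportions",
]

RINGS = ("nuclear", "inner", "cytoplasmic")


@dataclass
class GroupedDensities:
    """Per-cell particle densities (particles/um^2) keyed by condition."""

    groups: dict

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        for name, vals in self.groups.items():
            if len(vals) < 2:
                raise ValueError(f"group {name!r} has n={len(vals)} < 2")


@dataclass(frozen=True)
class RingCounts:
    """Particle counts per NPC ring zone."""

    nuclear: int
    inner: int
    cytoplasmic: int

    def __post_init__(self) -> None:
        if min(self.nuclear, self.inner, self.cytoplasmic) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return self.nuclear + self.inner + self.cytoplasmic

    def as_dict(self) -> dict:
        return {"nuclear": self.nuclear, "inner": self.inner, "cytoplasmic": self.cytoplasmic}

    @classmethod
    def from_positions(cls, positions: pd.DataFrame, single_particle_only: bool = False):
        """Tally ring labels from a mapped position table.

        With ``single_particle_only`` only particles in NPCs holding
        exactly one in-window particle are counted."""
        df = positions[positions["ring"].isin(RINGS)]
        if single_particle_only:
            per_npc = df.groupby("npc_id")["particle_id"].size()
            df = df[df["npc_id"].isin(per_npc.index[per_npc == 1])]
        c = df["ring"].value_counts()
        return cls(
            nuclear=int(c.get("nuclear", 0)),
            inner=int(c.get("inner", 0)),
            cytoplasmic=int(c.get("cytoplasmic", 0)),
        )


@dataclass
class DensityAnovaResult:
    """Normality checks plus one-way ANOVA (and fallback) on densities."""

    shapiro: dict  # group -> (W, p)
    f_statistic: float
    pvalue: float
    significant: bool
    normality_ok: bool
    kruskal: tuple | None = None  # (H, p) when normality fails
    warnings: list = field(default_factory=list)


def density_anova(groups, alpha: float = 0.05) -> DensityAnovaResult:
    """Shapiro-Wilk per group, then one-way ANOVA across groups.

    If any group fails the normality check at ``alpha``, a Kruskal-Wallis
    test is reported alongside the ANOVA with a warning.
    """
    if isinstance(groups, dict):
        groups = GroupedDensities(groups)
    data = groups.groups
    if len(data) < 2:
        raise ValueError("need >= 2 groups")
    shapiro = {}
    warnings = []
    normality_ok = True
    for name, vals in data.items():
        if len(vals) < 3:
            shapiro[name] = (float("nan"), float("nan"))
            warnings.append(f"group {name!r}: n < 3, Shapiro-Wilk skipped")
            continue
        w, p = sps.shapiro(vals)
        shapiro[name] = (float(w), float(p))
        if p < alpha:
            normality_ok = False
            warnings.append(f"group {name!r}: normality rejected (Shapiro-Wilk p={p:.3g})")
    f, p = sps.f_oneway(*data.values())
    kruskal = None
    if not normality_ok:
        h, pk = sps.kruskal(*data.values())
        kruskal = (float(h), float(pk))
        warnings.append("normality failed in >= 1 group: Kruskal-Wallis reported alongside")
    return DensityAnovaResult(
        shapiro=shapiro,
        f_statistic=float(f),
        pvalue=float(p),
        significant=bool(p < alpha),
        normality_ok=normality_ok,
        kruskal=kruskal,
        warnings=warnings,
    )


def _pair_permutation_pvalue(
    n_a: int, n_b: int, n_resamples: int | None, rng: np.random.Generator | None
) -> float:
    """Two-sided p for the count difference under uniform label permutation.

    Null: each of the n = n_a + n_b particles falls in ring A or B with
    probability 1/2, so n_a ~ Binomial(n, 1/2).  Exact by default;
    Monte-Carlo with ``n_resamples`` draws when requested.
    """
    n = n_a + n_b
    obs = abs(n_a - n_b)
    if n_resamples is None:
        k = np.arange(n + 1)
        pmf = sps.binom.pmf(k, n, 0.5)
        return float(pmf[np.abs(2 * k - n) >= obs].sum())
    draws = (rng or np.random.default_rng()).binomial(n, 0.5, size=n_resamples)
    hits = int(np.sum(np.abs(2 * draws - n) >= obs))
    return (hits + 1) / (n_resamples + 1)


def _holm(pvals: dict) -> dict:
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    adj, running = {}, 0.0
    for rank, (key, p) in enumerate(items):
        running = max(running, min(1.0, (m - rank) * p))
        adj[key] = running
    return adj


def ring_distribution_test(
    counts: RingCounts,
    method: str = "permutation",
    n_resamples: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pairwise tests of equal particle share between adjacent ring zones.

    ``method="permutation"`` (default): exact (or Monte-Carlo) uniform
    label-permutation test of the count split within each pair.
    ``method="mann-whitney"``: U test on the binary per-particle ring
    indicators of the pair.  Raw p-values are reported together with
    Holm-adjusted ones.
    """
    if method not in ("permutation", "mann-whitney"):
        raise ValueError(f"unknown method {method!r}")
    c = counts.as_dict()
    pairs = [("nuclear", "inner"), ("inner", "cytoplasmic"), ("nuclear", "cytoplasmic")]
    rng = np.random.default_rng(seed)
    pvals = {}
    for a, b in pairs:
        n_a, n_b = c[a], c[b]
        if n_a + n_b == 0:
            raise ValueError(f"empty ring pair ({a}, {b})")
        if n_a + n_b < 5:
            raise ValueError(f"pair ({a}, {b}): total {n_a + n_b} < 5, test unreliable")
        if method == "permutation":
            p = _pair_permutation_pvalue(n_a, n_b, n_resamples, rng)
        else:
            x = np.r_[np.ones(n_a), np.zeros(n_b)]  # indicator: particle is in ring a
            y = np.r_[np.zeros(n_a), np.ones(n_b)]  # indicator: particle is in ring b
            p = float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        pvals[(a, b)] = p
    holm = _holm(pvals)
    rows = [
        {
            "ring_a": a,
            "ring_b": b,
            "n_a": c[a],
            "n_b": c[b],
            "method": method,
            "pvalue": pvals[(a, b)],
            "pvalue_holm": holm[(a, b)],
        }
        for a, b in pairs
    ]
    return pd.DataFrame(rows)


def ring_proportions(counts: RingCounts) -> dict:
    """Integer ring percentages summing exactly to 100.

    Rounded by the largest-remainder rule: floor each share, then hand the
    remaining points to the largest fractional remainders.
    """
    if counts.total <= 0:
        raise ValueError("total count must be > 0")
    raw = {k: 100.0 * v / counts.total for k, v in counts.as_dict().items()}
    floors = {k: int(math.floor(v)) for k, v in raw.items()}
    short = 100 - sum(floors.values())
    remainders = sorted(raw, key=lambda k: raw[k] - floors[k], reverse=True)
    for k in remainders[:short]:
        floors[k] += 1
    return floors
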