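"""Ecosystem metabolism: flux-identity closure and the NEP statistical analysis.

The three identities linking the major metabolic fluxes are

    NEP = GPP - R_e        (net ecosystem production)
    NEP = NPP - R_h        (heterotrophic balance)
    NPP = GPP - R_a        (autotrophic balance)

with R_e = R_a + R_h the ecosystem respiration.  When a study reports two
members of an identity, the third is derivable; :func:`close_flux_triplet`
iterates the identities to a fixpoint and flags over-determined,
inconsistent triplets.

The NEP analysis follows the standard path for heterogeneous-variance
ecological data: per-ecosystem two-sided one-sample t-tests against zero
with 95% confidence intervals, the probability p+ of a positive NEP
observation under a normal fit to the data (Phi(mean/sd), sd the sample
standard deviation — a statement about the data distribution, not the
mean's sampling distribution), Bartlett's test to document variance
heterogeneity, a tie-corrected Kruskal-Wallis rank test across ecosystems,
and Siegel-Castellan pairwise mean-rank comparisons compressed into a
compact letter display.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError
from .records import Ecosystem

logger = logging.getLogger("crossflux")

__all__ = [
    "MetabolismTriplet",
    "TripletClosure",
    "close_flux_triplet",
    "NEPTestResult",
    "nep_ttest",
    "BartlettResult",
    "bartlett_test",
    "KWResult",
    "kruskal_wallis",
    "posthoc_rank_letters",
    "nep_analysis",
]


@dataclass
class MetabolismTriplet:
    """GPP / respiration / production members, any of which may be unknown."""

    gpp: Optional[float] = None
    r_e: Optional[float] = None
    nep: Optional[float] = None
    npp: Optional[float] = None
    r_a: Optional[float] = None
    r_h: Optional[float] = None


@dataclass
class TripletClosure:
    triplet: MetabolismTriplet
    derived: tuple[str, ...] = ()
    consistent: bool = True
    residuals: dict[str, float] = field(default_factory=dict)


# each identity as (member, (operand_a, operand_b, sign)): member = a + sign*b
_IDENTITIES = {
    "nep_gpp_re": ("nep", "gpp", "r_e"),  # nep = gpp - r_e
    "nep_npp_rh": ("nep", "npp", "r_h"),  # nep = npp - r_h
    "npp_gpp_ra": ("npp", "gpp", "r_a"),  # npp = gpp - r_a
}


def close_flux_triplet(
    triplet: MetabolismTriplet, rtol: float = 1e-6
) -> TripletClosure:
    """Fill every member derivable from the metabolism identities.

    Iterates until fixpoint; records which members were derived.  If an
    identity is fully determined but violated beyond ``rtol`` (relative to
    the largest member magnitude, floored at 1), the closure is flagged
    inconsistent with the residual.
    """
    t = replace(triplet)
    derived: list[str] = []
    residuals: dict[str, float] = {}

    changed = True
    while changed:
        changed = False
        for name, (s, a, b) in _IDENTITIES.items():
            vs, va, vb = getattr(t, s), getattr(t, a), getattr(t, b)
            known = [v is not None for v in (vs, va, vb)]
            if all(known):
                resid = va - vb - vs
                scale = max(1.0, abs(vs), abs(va), abs(vb))
                if abs(resid) > rtol * scale and name not in residuals:
                    residuals[name] = resid
                continue
            if sum(known) != 2:
                continue
            if vs is None:
                setattr(t, s, va - vb)
                derived.append(s)
            elif va is None:
                setattr(t, a, vs + vb)
                derived.append(a)
            else:
                setattr(t, b, va - vs)
                derived.append(b)
            changed = True
    return TripletClosure(
        triplet=t,
        derived=tuple(derived),
        consistent=not residuals,
        residuals=residuals,
    )


@dataclass
class NEPTestResult:
    """One-sample t-test of mean NEP against zero, plus the normal-model p+."""

    ecosystem: Optional[str]
    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    t_stat: float
    df: int
    p_two_sided: float
    p_plus: float
    degenerate: bool = False


def nep_ttest(
    values: Sequence[float], ecosystem=None, alpha: float = 0.05
) -> NEPTestResult:
    """Two-sided one-sample t-test of NEP against 0 with 95% CI and p+.

    p+ = Phi(mean / sd) is the probability that a random NEP observation is
    positive under a normal fit to the sample.  Zero-variance samples return
    a degenerate result with p+ in {0, 1/2, 1} by the sign of the mean.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise InsufficientDataError(f"need at least 2 NEP values, got {n}")
    name = ecosystem.value if isinstance(ecosystem, Ecosystem) else ecosystem
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        p_plus = 0.5 if mean == 0 else (1.0 if mean > 0 else 0.0)
        return NEPTestResult(
            name, n, mean, 0.0, mean, mean, math.nan, n - 1, math.nan, p_plus, True
        )
    se = sd / math.sqrt(n)
    t_stat = mean / se
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    tq = stats.t.ppf(1.0 - alpha / 2.0, df)
    p_plus = float(stats.norm.cdf(mean / sd))
    return NEPTestResult(
        name, n, mean, sd, mean - tq * se, mean + tq * se, t_stat, df, p, p_plus
    )


@dataclass
class BartlettResult:
    statistic: float
    p: float
    k: int
    excluded: tuple[str, ...] = ()


def bartlett_test(groups: Mapping[str, Sequence[float]]) -> BartlettResult:
    """Bartlett's test of variance homogeneity across ecosystem groups.

    Groups with fewer than 2 observations are excluded with a warning; the
    result documents why the nonparametric path is taken downstream.
    """
    usable, excluded = {}, []
    for name, vals in groups.items():
        if len(vals) >= 2:
            usable[name] = np.asarray(vals, dtype=float)
        else:
            excluded.append(str(name))
            logger.warning("bartlett_test: group '%s' has n < 2, excluded", name)
    if len(usable) < 2:
        raise InsufficientDataError("Bartlett's test needs at least 2 groups with n >= 2")
    if all(v.std(ddof=1) == 0 for v in usable.values()):
        return BartlettResult(0.0, 1.0, len(usable), tuple(excluded))
    stat, p = stats.bartlett(*usable.values())
    return BartlettResult(float(stat), float(p), len(usable), tuple(excluded))


@dataclass
class KWResult:
    """Kruskal-Wallis rank test with optional post-hoc letter display."""

    chi2: float
    df: int
    n_total: int
    p: float
    group_sizes: dict[str, int]
    letters: Optional[dict[str, str]] = None


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> KWResult:
    """Tie-corrected Kruskal-Wallis H across groups; chi-square tail p.

    Empty groups are excluded with a warning; fully identical observations
    give chi2 = 0, p = 1.
    """
    usable = {
        str(name): np.asarray(vals, dtype=float)
        for name, vals in groups.items()
        if len(vals) > 0
    }
    for name in set(map(str, groups)) - set(usable):
        logger.warning("kruskal_wallis: group '%s' is empty, excluded", name)
    if len(usable) < 2:
        raise InsufficientDataError("Kruskal-Wallis needs at least 2 non-empty groups")
    n_total = sum(v.size for v in usable.values())
    sizes = {k: int(v.size) for k, v in usable.items()}
    pooled = np.concatenate(list(usable.values()))
    if np.all(pooled == pooled[0]):
        return KWResult(0.0, len(usable) - 1, n_total, 1.0, sizes)
    stat, p = stats.kruskal(*usable.values())
    return KWResult(float(stat), len(usable) - 1, n_total, float(p), sizes)


def _compact_letter_display(
    names: Sequence[str], significant: set[frozenset]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display from a significant-pair set."""
    letter_sets: list[set[str]] = [set(names)]
    for i, j in itertools.combinations(names, 2):
        if frozenset((i, j)) not in significant:
            continue
        for ls in [s for s in letter_sets if i in s and j in s]:
            letter_sets.remove(ls)
            for reduced in (ls - {i}, ls - {j}):
                # absorb: keep only sets not contained in an existing one
                if reduced and not any(reduced <= other for other in letter_sets):
                    letter_sets.append(reduced)
        letter_sets = [
            s
            for s in letter_sets
            if not any(s < other for other in letter_sets)
        ]
    # deterministic letter order: by first member in input order
    order = {name: k for k, name in enumerate(names)}
    letter_sets.sort(key=lambda s: min(order[m] for m in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, list[str]] = {name: [] for name in names}
    for letter, ls in zip(alphabet, letter_sets):
        for member in ls:
            out[member].append(letter)
    return {name: "".join(sorted(v)) for name, v in out.items()}


def posthoc_rank_letters(
    groups: Mapping[str, Sequence[float]], family_alpha: float = 0.05
) -> dict[str, str]:
    """Siegel-Castellan multiple mean-rank comparisons as a letter display.

    Groups i, j differ when |Rbar_i - Rbar_j| >= z_{1 - alpha/(K(K-1))} *
    sqrt(N(N+1)/12 * (1/n_i + 1/n_j)); groups sharing any letter are not
    significantly different.  The partition is invariant to input order;
    letters are assigned in group enumeration order for reproducibility.
    """
    usable = {str(k): np.asarray(v, dtype=float) for k, v in groups.items() if len(v) > 0}
    names = list(usable)
    if len(names) == 1:
        return {names[0]: "a"}
    if not names:
        raise InsufficientDataError("no non-empty groups")
    pooled = np.concatenate([usable[n] for n in names])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    mean_ranks, sizes = {}, {}
    pos = 0
    for n in names:
        k = usable[n].size
        mean_ranks[n] = float(ranks[pos : pos + k].mean())
        sizes[n] = k
        pos += k
    kgroups = len(names)
    z_crit = stats.norm.ppf(1.0 - family_alpha / (kgroups * (kgroups - 1)))
    significant: set[frozenset] = set()
    for i, j in itertools.combinations(names, 2):
        crit = z_crit * math.sqrt(
            n_total * (n_total + 1) / 12.0 * (1.0 / sizes[i] + 1.0 / sizes[j])
        )
        if abs(mean_ranks[i] - mean_ranks[j]) >= crit:
            significant.add(frozenset((i, j)))
    return _compact_letter_display(names, significant)


@dataclass
class NEPAnalysis:
    per_ecosystem: list[NEPTestResult]
    bartlett: BartlettResult
    kruskal: KWResult


def nep_analysis(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> NEPAnalysis:
    """Full NEP pipeline stage: per-group t-tests, Bartlett, KW + letters."""
    per_eco = [
        nep_ttest(vals, ecosystem=name, alpha=alpha)
        for name, vals in groups.items()
        if len(vals) >= 2
    ]
    bart = bartlett_test(groups)
    kw = kruskal_wallis(groups)
    kw.letters = posthoc_rank_letters(groups, family_alpha=alpha)
    return NEPAnalysis(per_eco, bart, kw)
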