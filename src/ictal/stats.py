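"""Outcome statistics: exact 2x2 tests, rank tests, 2^-ΔΔCT relative
quantification, neurodegeneration classification, and the incidence /
frequency reduction arithmetic.

Conventions
-----------
* Fisher's exact test is two-sided by the point-probability rule: the
  p-value sums the hypergeometric probabilities (margins fixed) of every
  table no more probable than the observed one — the convention of
  mainstream statistical software.
* The Mann-Whitney U statistic uses midranks for ties and is reported as
  ``min(U1, U2)``.  The p-value is exact (full enumeration of group
  assignments, via a rank-sum distribution recursion) whenever
  ``min(n1, n2) <= 8`` and ``n1 + n2 <= 25``, otherwise a normal
  approximation with tie correction and continuity correction.
* ΔΔCT: ΔCT = CT(target) - geometric mean of the housekeeping CTs;
  ΔΔCT references the arithmetic mean ΔCT of the control group;
  fold change = 2^-ΔΔCT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

#: Default housekeeping (internal control) genes.
HOUSEKEEPING_GENES = ("ACTB", "GAPDH", "HPRT1")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = groups and columns = outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError("counts must be non-negative integers")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class GroupOutcome:
    """Per-group outcome counts (e.g. rats with >=1 seizure, seizure
    totals)."""

    label: str
    n_subjects: int
    n_positive: int = 0
    events_total: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_positive <= self.n_subjects:
            raise ValueError("need 0 <= n_positive <= n_subjects")
        if self.events_total < 0 or self.n_subjects < 1:
            raise ValueError("invalid group counts")

    @property
    def incidence(self) -> float:
        return self.n_positive / self.n_subjects

    @property
    def event_rate(self) -> float:
        """Events per subject."""
        return self.events_total / self.n_subjects


@dataclass
class QPCRPlate:
    """CT values for one qRT-PCR experiment.

    ``samples`` maps sample id -> {gene: CT}; ``groups`` maps sample id
    -> group label.  Every sample must carry all housekeeping genes.
    """

    samples: dict[str, dict[str, float]]
    groups: dict[str, str]
    housekeeping_genes: tuple[str, ...] = HOUSEKEEPING_GENES
    control_label: str = "control"

    def __post_init__(self) -> None:
        for sid, cts in self.samples.items():
            if sid not in self.groups:
                raise ValueError(f"sample {sid!r} has no group label")
            for gene in self.housekeeping_genes:
                if gene not in cts:
                    raise ValueError(
                        f"sample {sid!r} is missing housekeeping gene {gene!r}")
            for gene, ct in cts.items():
                if not ct > 0:
                    raise ValueError(f"CT values must be positive "
                                     f"({sid!r}/{gene!r} = {ct})")

    def housekeeping_geomean(self, sample_id: str) -> float:
        cts = self.samples[sample_id]
        return float(sps.gmean([cts[g] for g in self.housekeeping_genes]))


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value with margins fixed."""
    return float(sps.fisher_exact(table.as_array).pvalue)


def _rank_sum_distribution(double_ranks: np.ndarray,
                           n1: int) -> dict[int, int]:
    """Number of size-``n1`` subsets achieving each (doubled) rank sum.

    Midranks are half-integers, so doubling makes every sum an integer;
    the recursion is the standard subset-sum count over items.
    """
    counts: list[dict[int, int]] = [dict() for _ in range(n1 + 1)]
    counts[0][0] = 1
    for r in double_ranks:
        r = int(r)
        for k in range(n1 - 1, -1, -1):
            if counts[k]:
                for s, c in list(counts[k].items()):
                    counts[k + 1][s + r] = counts[k + 1].get(s + r, 0) + c
    return counts[n1]


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    Returns ``(U, p)`` with ``U = min(U1, U2)``.  The exact path
    enumerates the permutation distribution of the rank sum (midranks,
    so ties are handled exactly); larger samples use the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)

    if min(n1, n2) <= 8 and n1 + n2 <= 25:
        double = np.rint(2 * ranks).astype(np.int64)
        dist = _rank_sum_distribution(double, n1)
        total = math.comb(n1 + n2, n1)
        mean_double_u = n1 * n2  # E[2*U1]
        obs_dev = abs(2 * u1 - mean_double_u)
        hits = 0
        offset = n1 * (n1 + 1)  # 2 * n1(n1+1)/2
        for s2, c in dist.items():
            if abs((s2 - offset) - mean_double_u) >= obs_dev - 1e-9:
                hits += c
        p = hits / total
    else:
        p = float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="asymptotic").pvalue)
    return float(u), float(min(p, 1.0))


def ddct_fold_change(plate: QPCRPlate, gene: str) -> dict:
    """2^-ΔΔCT fold change of ``gene`` per sample and per group.

    Returns ``{"per_sample": {sid: fold}, "group_mean": {label: mean}}``.
    ΔΔCT is referenced to the mean ΔCT of the control group.
    """
    delta_ct = {}
    for sid, cts in plate.samples.items():
        if gene not in cts:
            raise ValueError(f"sample {sid!r} lacks target gene {gene!r}")
        delta_ct[sid] = cts[gene] - plate.housekeeping_geomean(sid)
    controls = [d for sid, d in delta_ct.items()
                if plate.groups[sid] == plate.control_label]
    if not controls:
        raise ValueError(f"no samples in control group "
                         f"{plate.control_label!r}")
    ref = float(np.mean(controls))
    per_sample = {sid: float(2.0 ** -(d - ref)) for sid, d in delta_ct.items()}
    group_mean: dict[str, float] = {}
    for label in sorted(set(plate.groups.values())):
        folds = [per_sample[sid] for sid in per_sample
                 if plate.groups[sid] == label]
        group_mean[label] = float(np.mean(folds))
    return {"per_sample": per_sample, "group_mean": group_mean}


def fjb_protection_class(count_per_section: float) -> str:
    """Classify a hippocampal subregion by FluoroJade-B positive cells
    per section: more than 10 (i.e. 11 or more) marks the animal as
    degenerating; 10 or fewer as protected."""
    if count_per_section < 0:
        raise ValueError("cell count must be non-negative")
    return "degenerating" if count_per_section > 10 else "protected"


def incidence_reduction(treated: GroupOutcome,
                        reference: GroupOutcome) -> int:
    """Percent reduction in incidence (fraction of subjects positive)
    of the treated group relative to the reference, rounded to the
    nearest integer percent."""
    if reference.incidence <= 0:
        raise ValueError("reference incidence must be positive")
    return int(round(100.0 * (1.0 - treated.incidence / reference.incidence)))


def frequency_reduction(treated: GroupOutcome,
                        reference: GroupOutcome) -> float:
    """Percent reduction in per-subject event rate of the treated group
    relative to the reference."""
    if reference.event_rate <= 0:
        raise ValueError("reference event rate must be positive")
    return 100.0 * (1.0 - treated.event_rate / reference.event_rate)


def percent_of_day0(weights: dict) -> dict:
    """Body mass per day expressed as percent of day 0."""
    if 0 not in weights:
        raise ValueError("weights must include day 0")
    w0 = weights[0]
    if not w0 > 0:
        raise ValueError("day-0 mass must be positive")
    return {day: 100.0 * w / w0 for day, w in weights.items()}
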