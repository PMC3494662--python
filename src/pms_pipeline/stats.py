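"""Transmission, mosaicism and lethality statistics.

Implements the inheritance-side analyses: Pearson chi-square tests on
progeny count tables (independence of sex and carrier status; goodness of
fit against autosomal-dominant expectations; cross-stage distribution
comparisons), Welch's unequal-variance t-test from summary statistics,
germline-mosaicism estimation from sperm-FISH carrier counts with an exact
binomial confidence interval, and the reproduction-record procedure that
bounds when deletion-carrying male conceptuses die: filter artifact
inseminations, then convert each failed insemination's interval to the next
reproductive event into an upper bound on conceptus survival.

No continuity correction is applied anywhere: all chi-square statistics are
plain Pearson statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .datatypes import TRANSMISSION_CELLS, AIRecord, TransmissionCounts


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside [0, 1]")


# ---------------------------------------------------------------------------
# chi-square tests


def chi2_independence_2x2(table) -> TestResult:
    """Pearson chi-square test of independence on a 2x2 table (df = 1).

    No Yates continuity correction. All four marginals must be positive.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"table must be 2x2, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("negative cell count")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in 2x2 table")
    stat, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return TestResult(float(stat), float(dof), float(p), "pearson-chi2-independence")


def chi2_goodness_of_fit(observed, expected_proportions) -> TestResult:
    """Pearson goodness-of-fit chi-square (df = k - 1)."""
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and expected_proportions differ in length")
    if not np.isclose(props.sum(), 1.0):
        raise ValueError(f"expected proportions sum to {props.sum()}, not 1")
    if obs.sum() <= 0:
        raise ValueError("total observed count must be positive")
    if (props <= 0).any():
        raise ValueError("zero expected proportion")
    expected = props * obs.sum()
    stat, p = sps.chisquare(obs, expected)
    return TestResult(float(stat), float(len(obs) - 1), float(p), "pearson-chi2-gof")


def stage_comparison(
    observed: TransmissionCounts,
    reference: TransmissionCounts,
) -> TestResult:
    """Goodness of fit of a later stage's four-cell table against an earlier
    stage's proportions.

    The earlier developmental stage supplies the reference proportions, the
    later one the observed counts (a carrier/sex category can only be lost,
    not gained, between stages). If the reference has an empty cell, cells
    are pooled over sex into carrier vs wild-type before testing.
    """
    obs = observed.as_vector()
    ref = reference.as_vector()
    if ref.sum() == 0 or obs.sum() == 0:
        raise ValueError("empty count table")
    if (ref == 0).any():
        # pool over sex: (wt, del)
        obs = np.array([obs[0] + obs[2], obs[1] + obs[3]])
        ref = np.array([ref[0] + ref[2], ref[1] + ref[3]])
        if (ref == 0).any():
            raise ValueError("zero reference cell after pooling")
    res = chi2_goodness_of_fit(obs, ref / ref.sum())
    return TestResult(res.statistic, res.df, res.p, "stage-gof")


# ---------------------------------------------------------------------------
# Welch's t


def welch_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TestResult:
    """Welch's unequal-variance t-test from group summaries.

    Degrees of freedom by the Welch-Satterthwaite approximation; two-sided p.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), "welch-t")


# ---------------------------------------------------------------------------
# mosaicism


@dataclass(frozen=True)
class MosaicismEstimate:
    """Germline mosaicism from a carrier-sperm count.

    Each mosaic (heterozygous) germline cell transmits the deletion to half
    its gametes, so mosaicism = 2 x carrier-sperm fraction, capped at 1. The
    confidence interval is the exact (Clopper-Pearson) binomial interval on
    the sperm fraction, doubled and capped.
    """

    k: int
    n: int
    sperm_fraction: float
    mosaicism: float
    ci_low: float
    ci_high: float
    ci_level: float


def mosaicism_from_sperm(k: int, n: int, ci_level: float = 0.95) -> MosaicismEstimate:
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    frac = k / n
    alpha = 1.0 - ci_level
    lo = sps.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = sps.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return MosaicismEstimate(
        k=k,
        n=n,
        sperm_fraction=frac,
        mosaicism=min(1.0, 2.0 * frac),
        ci_low=min(1.0, 2.0 * float(lo)),
        ci_high=min(1.0, 2.0 * float(hi)),
        ci_level=ci_level,
    )


def lethality_from_birth_counts(birth: TransmissionCounts) -> float:
    """Method-of-moments male-carrier lethality from a birth table.

    Carrier conceptions are sex-balanced, so the deficit of carrier males
    relative to carrier females at birth estimates the death probability:
    ``1 - n(M,del) / n(F,del)``, clipped to [0, 1].
    """
    f_del = birth.counts[("F", "del")]
    m_del = birth.counts[("M", "del")]
    if f_del == 0:
        raise ValueError("no carrier females at birth; lethality not estimable")
    return float(np.clip(1.0 - m_del / f_del, 0.0, 1.0))


# ---------------------------------------------------------------------------
# AI-record filtering and the lethality window


@dataclass(frozen=True)
class LethalityConfig:
    gestation_days: int = 285
    cycle_days: int = 21
    low_fertility_min_failures: int = 3
    adjacent_ai_max_gap_days: int = 1

    def __post_init__(self) -> None:
        if min(
            self.gestation_days,
            self.cycle_days,
            self.low_fertility_min_failures,
            self.adjacent_ai_max_gap_days,
        ) <= 0:
            raise ValueError("all lethality-config fields must be positive")


@dataclass(frozen=True)
class DiscardedRecord:
    record: AIRecord
    reason: str


def filter_ai_records(
    records: list[AIRecord], cfg: LethalityConfig | None = None
) -> tuple[list[AIRecord], list[DiscardedRecord]]:
    """Retain failure records usable for the lethality bound.

    Discard rules apply in a fixed order, each record attributed to the first
    matching rule so category counts stay disjoint:

    1. ``not_failure`` — successful inseminations;
    2. ``superovulation`` — inseminations after superovulation;
    3. ``adjacent_ai`` — inseminations followed by another insemination of the
       same cow within ``adjacent_ai_max_gap_days`` (same heat, double AI);
    4. ``low_fertility`` — all failures of cows with at least
       ``low_fertility_min_failures`` consecutive failures.
    """
    cfg = cfg or LethalityConfig()
    retained: list[AIRecord] = []
    discarded: list[DiscardedRecord] = []
    for r in records:
        if r.outcome != "failure":
            discarded.append(DiscardedRecord(r, "not_failure"))
        elif r.superovulation:
            discarded.append(DiscardedRecord(r, "superovulation"))
        elif (
            r.next_event == "ai"
            and r.next_event_day is not None
            and r.next_event_day - r.ai_day <= cfg.adjacent_ai_max_gap_days
        ):
            discarded.append(DiscardedRecord(r, "adjacent_ai"))
        elif r.consecutive_failures_for_cow >= cfg.low_fertility_min_failures:
            discarded.append(DiscardedRecord(r, "low_fertility"))
        else:
            retained.append(r)
    return retained, discarded


@dataclass(frozen=True)
class LethalityBound:
    record: AIRecord
    bound_days: int
    valid: bool  # non-positive bounds are inconsistent and excluded from the max


@dataclass
class LethalityWindow:
    bounds: list[LethalityBound]
    max_bound_days: int | None

    @property
    def n_valid(self) -> int:
        return sum(b.valid for b in self.bounds)


def lethality_window(
    records: list[AIRecord], cfg: LethalityConfig | None = None
) -> LethalityWindow:
    """Upper bounds on conceptus survival from failed-insemination intervals.

    For a failure followed by another insemination (a newly observed heat),
    the conceptus cannot have survived past
    ``(next_ai_day - ai_day) - cycle_days``; for a failure followed directly
    by a calving (an intervening unrecorded conception), past
    ``(calving_day - ai_day - gestation_days) - cycle_days``. Non-positive
    bounds are flagged inconsistent and excluded; the maximum over valid
    bounds is the overall window.
    """
    cfg = cfg or LethalityConfig()
    usable = [r for r in records if r.next_event != "none"]
    if not usable:
        raise ValueError("no record with a next event; lethality window undefined")
    bounds: list[LethalityBound] = []
    for r in usable:
        gap = r.next_event_day - r.ai_day
        if r.next_event == "ai":
            b = gap - cfg.cycle_days
        else:  # calving
            b = gap - cfg.gestation_days - cfg.cycle_days
        bounds.append(LethalityBound(r, int(b), b > 0))
    valid = [b.bound_days for b in bounds if b.valid]
    return LethalityWindow(bounds, max(valid) if valid else None)


# ---------------------------------------------------------------------------
# consolidated report


@dataclass
class InheritanceReport:
    """All transmission statistics for one cohort, in one serializable bundle."""

    sex_by_phenotype_independence: TestResult
    dominant_gof: TestResult
    stage_tests: dict[str, TestResult]
    mosaicism: list[MosaicismEstimate]
    lethality_estimate: float | None
    lethality: LethalityWindow | None
    sex_ratio_wt: float | None
    sex_ratio_carrier: float | None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def tr(t: TestResult) -> dict:
            return {
                "statistic": round(t.statistic, 4),
                "df": t.df,
                "p": float(f"{t.p:.3g}"),
                "method": t.method,
            }

        return {
            "sex_by_phenotype_independence": tr(self.sex_by_phenotype_independence),
            "dominant_gof": tr(self.dominant_gof),
            "stage_tests": {k: tr(v) for k, v in self.stage_tests.items()},
            "mosaicism": [
                {
                    "k": m.k,
                    "n": m.n,
                    "sperm_fraction": m.sperm_fraction,
                    "estimate": m.mosaicism,
                    "ci": [m.ci_low, m.ci_high],
                    "ci_level": m.ci_level,
                }
                for m in self.mosaicism
            ],
            "lethality_estimate": self.lethality_estimate,
            "max_bound_days": (
                self.lethality.max_bound_days if self.lethality else None
            ),
            "n_retained_ai": (len(self.lethality.bounds) if self.lethality else None),
            "sex_ratio_wt": self.sex_ratio_wt,
            "sex_ratio_carrier": self.sex_ratio_carrier,
            "notes": self.notes,
        }


def _as_2x2(counts: TransmissionCounts) -> np.ndarray:
    """Rows = sex (F, M), columns = carrier status (wt, del)."""
    c = counts.counts
    return np.array(
        [[c[("F", "wt")], c[("F", "del")]], [c[("M", "wt")], c[("M", "del")]]],
        dtype=float,
    )


def inheritance_report(
    birth: TransmissionCounts,
    sperm: TransmissionCounts | None = None,
    blastocyst: TransmissionCounts | None = None,
    sperm_experiments: list[tuple[int, int]] | None = None,
    ai_records: list[AIRecord] | None = None,
    lethality_cfg: LethalityConfig | None = None,
) -> InheritanceReport:
    """Assemble the full inheritance analysis for one cohort."""
    notes: list[str] = []
    indep = chi2_independence_2x2(_as_2x2(birth))
    gof = chi2_goodness_of_fit(birth.as_vector(), [0.25] * 4)

    stage_tests: dict[str, TestResult] = {}
    if sperm is not None and blastocyst is not None:
        stage_tests["sperm_vs_blastocyst"] = stage_comparison(blastocyst, sperm)
        stage_tests["blastocyst_vs_birth"] = stage_comparison(birth, blastocyst)
        stage_tests["sperm_vs_birth"] = stage_comparison(birth, sperm)

    mosaicism = [
        mosaicism_from_sperm(k, n) for k, n in (sperm_experiments or [])
    ]

    try:
        lethality_estimate = lethality_from_birth_counts(birth)
    except ValueError as e:
        lethality_estimate = None
        notes.append(str(e))

    window = None
    if ai_records:
        retained, discarded = filter_ai_records(ai_records, lethality_cfg)
        reasons = {}
        for d in discarded:
            reasons[d.reason] = reasons.get(d.reason, 0) + 1
        notes.append(f"AI records retained: {len(retained)}; discarded: {reasons}")
        if retained:
            window = lethality_window(retained, lethality_cfg)

    c = birth.counts
    sex_ratio_wt = (
        c[("M", "wt")] / c[("F", "wt")] if c[("F", "wt")] else None
    )
    sex_ratio_carrier = (
        c[("M", "del")] / c[("F", "del")] if c[("F", "del")] else None
    )
    return InheritanceReport(
        sex_by_phenotype_independence=indep,
        dominant_gof=gof,
        stage_tests=stage_tests,
        mosaicism=mosaicism,
        lethality_estimate=lethality_estimate,
        lethality=window,
        sex_ratio_wt=sex_ratio_wt,
        sex_ratio_carrier=sex_ratio_carrier,
        notes=notes,
    )
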