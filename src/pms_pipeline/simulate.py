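"""Seeded synthetic-cohort generator.

Generates every input the pipeline consumes — pedigree, SNP-array genotypes,
windowed sequencing depth, breakpoint read evidence, stage-wise transmission
counts and artificial-insemination (AI) records — under a single generative
model: a founder sire who is a somatic/germline mosaic for a multi-megabase
hemizygous deletion, transmitting it to half the gametes of his mosaic
germline fraction ``m``, with deletion-carrying male conceptuses dying before
birth with probability ``lambda`` (male-specific embryonic lethality).

Design points that drive the downstream analyses:

* The founder's own array genotype is his constitutional diploid genotype;
  mosaicism affects transmission only.
* A carrier offspring is hemizygous inside the deletion: the array reports the
  remaining maternal allele as a homozygous call (or a no-call at a small
  rate), which is what produces clustered sire-offspring opposite-homozygote
  Mendelian errors and affected-only heterozygosity depletion.
* Read depth halves over the deletion in a carrier; read pairs spanning the
  deletion show inflated insert sizes; reads crossing the breakpoint are
  soft-clipped and carry the junction sequence, including the non-template
  micro-insertion.

Ground truth (deletion coordinates, inserted sequence, mosaicism, lethality,
latent conceptus death-day bound) is retained for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    TRANSMISSION_CELLS,
    AIRecord,
    DepthProfile,
    GenotypeMatrix,
    MarkerMap,
    PairEvidence,
    Pedigree,
    PedigreeRecord,
    Region,
    TransmissionCounts,
)
from .reference import SyntheticReference

SIRE_ID = "V"


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator, with the study-design defaults.

    Cohort sizes default to the real design: 19 unaffected and 3 affected
    genotyped progeny, 76 recorded births, 165 sexed-and-genotyped
    blastocysts, two sperm-FISH experiments of 1000 scored spermatozoa each,
    26 successful and 35 failed AI with a 1/6/8 split of discardable
    artifacts. Germline mosaicism defaults to 0.68 (the midpoint of a 66-70%
    range) and male-carrier lethality to 0.86 (the deficit of carrier males
    at birth implied by a 14:2 female:male carrier ratio).
    """

    seed: int = 0
    # genome / markers
    chrom: str = "2"
    chrom_length: int = 120_000_000
    n_markers: int = 6000
    maf_range: tuple[float, float] = (0.05, 0.5)
    # deletion truth
    deletion_start_flank: int = 49_422_588  # last retained base before deletion
    deletion_end_flank: int = 53_130_732    # first retained base after deletion
    inserted_seq: str = "ACAT"
    # transmission model
    germline_mosaicism: float = 0.68
    male_lethality: float = 0.86
    # cohort sizes
    n_unaffected_genotyped: int = 19
    n_affected_genotyped: int = 3
    n_progeny_birth: int = 76
    n_sperm_scored: int = 1000
    n_sperm_experiments: int = 2
    n_blastocysts: int = 165
    # array noise
    genotyping_error_rate: float = 0.002
    hemizygote_nocall_rate: float = 0.02
    # sequencing
    mean_depth: float = 12.0
    depth_window_bp: int = 20_000
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    read_len: int = 100
    n_junction_fragments: int = 40
    n_background_fragments: int = 20
    # AI records
    n_ai_success: int = 26
    n_ai_failures: int = 35
    n_superovulation_artifacts: int = 1
    n_adjacent_ai_artifacts: int = 6
    n_low_fertility_artifact_records: int = 8
    max_death_day: int = 88          # latent bound on conceptus death (days post AI)
    min_death_day: int = 8
    gestation_days: int = 285
    cycle_days: int = 21

    def validate(self) -> None:
        rates = {
            "germline_mosaicism": self.germline_mosaicism,
            "male_lethality": self.male_lethality,
            "genotyping_error_rate": self.genotyping_error_rate,
            "hemizygote_nocall_rate": self.hemizygote_nocall_rate,
        }
        for name, v in rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.deletion_end_flank < self.deletion_start_flank + 2:
            raise ValueError("deletion_end_flank must be >= start_flank + 2")
        if self.deletion_end_flank > self.chrom_length:
            raise ValueError("deletion lies outside the chromosome")
        lo, hi = self.maf_range
        if not (0 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 <= lo <= hi <= 0.5")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be non-negative")
        nonneg = (
            self.n_markers, self.n_progeny_birth, self.n_sperm_scored,
            self.n_blastocysts, self.n_ai_success, self.n_ai_failures,
        )
        if any(v < 0 for v in nonneg):
            raise ValueError("cohort sizes must be non-negative")
        n_art = (
            self.n_superovulation_artifacts
            + self.n_adjacent_ai_artifacts
            + self.n_low_fertility_artifact_records
        )
        if n_art > self.n_ai_failures:
            raise ValueError("artifact records exceed total AI failures")
        if self.max_death_day < self.min_death_day:
            raise ValueError("max_death_day must be >= min_death_day")


@dataclass
class Truth:
    """Ground truth retained alongside a simulated cohort."""

    chrom: str
    left_flank: int
    right_flank: int
    inserted_seq: str
    germline_mosaicism: float
    male_lethality: float
    max_death_day: int
    carrier_ids: list[str] = field(default_factory=list)

    @property
    def deleted_interval(self) -> Region:
        return Region(self.chrom, self.left_flank + 1, self.right_flank - 1, "deletion")

    @property
    def deletion_length(self) -> int:
        return self.right_flank - self.left_flank - 1

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CohortBundle:
    """A complete simulated dataset plus its generating truth."""

    config: SimulationConfig
    truth: Truth
    pedigree: Pedigree
    marker_map: MarkerMap
    genotypes: GenotypeMatrix
    depth_carrier: DepthProfile
    depth_control: DepthProfile
    pairs: PairEvidence
    counts: dict[str, TransmissionCounts]
    sperm_experiments: list[tuple[int, int]]  # (carrier count k, scored n) per FISH run
    ai_records: list[AIRecord]
    reference: SyntheticReference


# ---------------------------------------------------------------------------
# pedigree + markers


def build_pedigree(cfg: SimulationConfig) -> Pedigree:
    """Sire, one dam per progeny, affected daughters and unaffected half-sibs.

    With zero germline mosaicism no deletion is ever transmitted, so the
    affected subcohort is empty regardless of the configured size.
    """
    records = [PedigreeRecord(SIRE_ID, None, None, "M", "unaffected")]
    n_u = cfg.n_unaffected_genotyped
    n_a = cfg.n_affected_genotyped if cfg.germline_mosaicism > 0 else 0
    for i in range(1, n_u + 1):
        records.append(PedigreeRecord(f"DU{i:02d}", None, None, "F", "unknown"))
    for i in range(1, n_a + 1):
        records.append(PedigreeRecord(f"DA{i:02d}", None, None, "F", "unknown"))
    for i in range(1, n_u + 1):
        sex = "F" if i % 2 else "M"
        records.append(
            PedigreeRecord(f"U{i:02d}", SIRE_ID, f"DU{i:02d}", sex, "unaffected")
        )
    for i in range(1, n_a + 1):
        records.append(
            PedigreeRecord(f"A{i:02d}", SIRE_ID, f"DA{i:02d}", "F", "affected")
        )
    return Pedigree(records)


def build_marker_map(cfg: SimulationConfig, rng: np.random.Generator) -> MarkerMap:
    # draw-and-dedupe; collisions are vanishingly rare at n << chrom_length
    pos = np.unique(rng.integers(1, cfg.chrom_length + 1, size=cfg.n_markers))
    while pos.size < cfg.n_markers:
        extra = rng.integers(1, cfg.chrom_length + 1, size=cfg.n_markers - pos.size)
        pos = np.unique(np.concatenate([pos, extra]))
    lo, hi = cfg.maf_range
    maf = rng.uniform(lo, hi, size=cfg.n_markers)
    t = pd.DataFrame(
        {
            "marker_id": [f"M{i:06d}" for i in range(1, cfg.n_markers + 1)],
            "chrom": cfg.chrom,
            "pos": pos.astype(np.int64),
            "allele_a": "A",
            "allele_b": "B",
            "maf": maf,
        }
    )
    return MarkerMap(t)


# ---------------------------------------------------------------------------
# genotypes


def _draw_diploid(maf: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Hardy-Weinberg dosage draw; maf is the allele-B frequency per marker."""
    return (rng.random(maf.shape) < maf).astype(np.int8) + (
        rng.random(maf.shape) < maf
    ).astype(np.int8)


def _transmit(parent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per marker from a diploid dosage vector (0/1 allele-B copy)."""
    gam = np.where(parent == 2, 1, 0).astype(np.int8)
    het = parent == 1
    gam[het] = (rng.random(het.sum()) < 0.5).astype(np.int8)
    return gam


def simulate_genotypes(
    pedigree: Pedigree,
    marker_map: MarkerMap,
    truth: Truth,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Array genotypes for sire, genotyped progeny and the affected dams.

    Carrier progeny lose the paternal allele at every marker inside the
    deleted interval: the call collapses to homozygosity for the maternal
    allele, with a no-call at ``hemizygote_nocall_rate``. Per-call flip errors
    are applied at ``genotyping_error_rate`` afterwards.
    """
    maf = marker_map.table["maf"].to_numpy()
    pos = marker_map.positions
    inside = (pos > truth.left_flank) & (pos < truth.right_flank)
    n_mark = len(marker_map)

    sire = _draw_diploid(maf, rng)
    dams: dict[str, np.ndarray] = {}
    for rec in pedigree.records:
        if rec.animal_id.startswith(("DU", "DA")):
            dams[rec.animal_id] = _draw_diploid(maf, rng)

    sample_ids: list[str] = [SIRE_ID]
    rows: list[np.ndarray] = [sire.copy()]
    carriers = set(truth.carrier_ids)
    for rec in pedigree.progeny_of(SIRE_ID):
        maternal = _transmit(dams[rec.dam_id], rng)
        paternal = _transmit(sire, rng)
        calls = (maternal + paternal).astype(np.int8)
        if rec.animal_id in carriers:
            # hemizygous: array sees only the maternal allele
            calls[inside] = (2 * maternal[inside]).astype(np.int8)
            nocall = inside & (rng.random(n_mark) < cfg.hemizygote_nocall_rate)
            calls[nocall] = MISSING
        sample_ids.append(rec.animal_id)
        rows.append(calls)
    # affected dams are genotyped too (they anchor the hemizygosity check)
    for rec in pedigree.progeny_of(SIRE_ID):
        if rec.phenotype == "affected":
            sample_ids.append(rec.dam_id)
            rows.append(dams[rec.dam_id].copy())

    calls = np.vstack(rows)
    if cfg.genotyping_error_rate > 0:
        err = (rng.random(calls.shape) < cfg.genotyping_error_rate) & (calls != MISSING)
        # flip to one of the two other valid calls, uniformly
        shift = rng.integers(1, 3, size=calls.shape)
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    return GenotypeMatrix(sample_ids, marker_map.marker_ids, calls)


# ---------------------------------------------------------------------------
# depth


def simulate_depth(
    truth: Truth, cfg: SimulationConfig, carrier: bool, rng: np.random.Generator
) -> DepthProfile:
    """Windowed coverage: Poisson(mean_depth x copy/2) per window.

    Windows partially overlapping the deletion get the coverage expected from
    their diploid/hemizygous base fractions.
    """
    w = cfg.depth_window_bp
    n_win = cfg.chrom_length // w
    starts = np.arange(n_win, dtype=np.int64) * w + 1
    ends = starts + w - 1
    expectation = np.full(n_win, cfg.mean_depth, dtype=float)
    if carrier:
        del_start, del_end = truth.left_flank + 1, truth.right_flank - 1
        ov = np.clip(
            np.minimum(ends, del_end) - np.maximum(starts, del_start) + 1, 0, None
        )
        frac_deleted = ov / w
        expectation *= 1.0 - 0.5 * frac_deleted
    depth = rng.poisson(expectation).astype(float)
    windows = pd.DataFrame(
        {"chrom": truth.chrom, "start": starts, "end": ends, "depth": depth}
    )
    return DepthProfile(windows, genome_median_depth=float(np.median(depth)))


# ---------------------------------------------------------------------------
# read-pair / clip evidence


def _sample_to_ref(s: int, truth: Truth) -> int:
    """Map a carrier-sample coordinate to the reference coordinate."""
    n_ins = len(truth.inserted_seq)
    if s <= truth.left_flank:
        return s
    if s <= truth.left_flank + n_ins:
        raise ValueError("position inside inserted sequence has no reference image")
    return (s - truth.left_flank - n_ins) + truth.right_flank - 1


def simulate_pairs(
    truth: Truth,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    reference: SyntheticReference,
) -> PairEvidence:
    """Paired-end evidence from a carrier sample around the deletion junction.

    The carrier chromosome is reference[..left_flank] + inserted_seq +
    reference[right_flank..]. Fragments are drawn in carrier coordinates;
    each read aligns to the flank giving the longer match, with the remainder
    soft-clipped. A pair whose reads anchor on opposite flanks shows an
    observed insert inflated by (deletion length - insertion length).
    """
    R = cfg.read_len
    n_ins = len(truth.inserted_seq)
    lf, rf = truth.left_flank, truth.right_flank
    rows: list[tuple] = []

    def read_alignment(s: int) -> tuple[int, str, str]:
        """(ref pos of first aligned base, clip_side, clipped_seq) for a read
        covering carrier positions s..s+R-1."""
        e = s + R - 1
        if e <= lf:
            return s, "none", ""
        if s > lf + n_ins:
            return _sample_to_ref(s, truth), "none", ""
        anchor_left = max(0, lf - s + 1)
        anchor_right = max(0, e - (lf + n_ins))
        if anchor_left >= anchor_right:
            # align on the left flank, clip the tail crossing the junction
            n_clip = R - anchor_left
            n_from_right = max(0, n_clip - n_ins)
            clipped = truth.inserted_seq[: min(n_clip, n_ins)]
            if n_from_right:
                clipped += reference.fetch(rf, rf + n_from_right - 1)
            return s, "right", clipped
        # align on the right flank, clip the prefix
        n_clip = R - anchor_right
        n_from_left = max(0, n_clip - n_ins)
        clipped = ""
        if n_from_left:
            clipped = reference.fetch(lf - n_from_left + 1, lf)
        clipped += truth.inserted_seq[max(0, n_ins - (n_clip - n_from_left)) :]
        return rf, "left", clipped

    def emit_fragment(idx: int, s: int, frag_len: int, tag: str) -> None:
        left_start = s
        right_start = s + frag_len - R
        if right_start <= left_start:  # degenerate tiny fragment
            return
        p1, side1, clip1 = read_alignment(left_start)
        p2, side2, clip2 = read_alignment(right_start)
        # outer insert in reference coordinates, as an aligner would report
        aligned2 = R - len(clip2)
        right_end_ref = p2 + aligned2 - 1
        insert = right_end_ref - p1 + 1
        rows.append((f"{tag}{idx:04d}/1", truth.chrom, p1, p2, insert, side1, clip1))
        rows.append((f"{tag}{idx:04d}/2", truth.chrom, p2, p1, insert, side2, clip2))

    span = int(cfg.insert_mean + 4 * cfg.insert_sd)
    for i in range(cfg.n_junction_fragments):
        frag_len = max(2 * R + 2, int(round(rng.normal(cfg.insert_mean, cfg.insert_sd))))
        s = int(rng.integers(lf - span, lf + 2))
        emit_fragment(i, s, frag_len, "J")
    bg_anchor = max(1, lf - 2_000_000)
    for i in range(cfg.n_background_fragments):
        frag_len = max(2 * R + 2, int(round(rng.normal(cfg.insert_mean, cfg.insert_sd))))
        s = int(rng.integers(bg_anchor, bg_anchor + 100_000))
        emit_fragment(i, s, frag_len, "B")

    table = pd.DataFrame(
        rows,
        columns=["read_id", "chrom", "pos", "mate_pos", "insert", "clip_side", "clipped_seq"],
    )
    return PairEvidence(table, read_len=R)


# ---------------------------------------------------------------------------
# transmission counts


def _cell_probs_at_conception(m: float) -> np.ndarray:
    """(F-wt, F-del, M-wt, M-del) probabilities before any lethality."""
    q = m / 2.0  # carrier-gamete fraction: each mosaic germ cell is heterozygous
    return np.array([(1 - q) / 2, q / 2, (1 - q) / 2, q / 2])


def simulate_sperm_counts(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[TransmissionCounts, list[tuple[int, int]]]:
    """Sperm-FISH style counts: per-experiment carrier counts plus the pooled
    four-cell table (sex read off the sex chromosome probe)."""
    probs = _cell_probs_at_conception(cfg.germline_mosaicism)
    total = np.zeros(4, dtype=np.int64)
    experiments: list[tuple[int, int]] = []
    for _ in range(cfg.n_sperm_experiments):
        cells = rng.multinomial(cfg.n_sperm_scored, probs)
        total += cells
        experiments.append((int(cells[1] + cells[3]), int(cfg.n_sperm_scored)))
    return TransmissionCounts.from_vector("sperm", total), experiments


def simulate_blastocyst_counts(
    cfg: SimulationConfig, rng: np.random.Generator
) -> TransmissionCounts:
    """Blastocysts sample conceptions with no carrier or sex selection."""
    probs = _cell_probs_at_conception(cfg.germline_mosaicism)
    cells = rng.multinomial(cfg.n_blastocysts, probs)
    return TransmissionCounts.from_vector("blastocyst", cells)


def simulate_birth_counts(
    n_births: int, m: float, male_lethality: float, rng: np.random.Generator
) -> TransmissionCounts:
    """Births: conception-cell probabilities thinned by male-carrier death.

    Each male carrier conceptus independently dies before birth with
    probability ``male_lethality``; the observed table is a multinomial over
    the surviving-category distribution.
    """
    probs = _cell_probs_at_conception(m)
    weights = probs * np.array([1.0, 1.0, 1.0, 1.0 - male_lethality])
    weights = weights / weights.sum()
    cells = rng.multinomial(n_births, weights)
    return TransmissionCounts.from_vector("birth", cells)


# ---------------------------------------------------------------------------
# AI records


def simulate_ai_records(
    cfg: SimulationConfig, rng: np.random.Generator
) -> list[AIRecord]:
    """AI events: successes, clean failures and the three artifact classes.

    A clean failure carries a latent conceptus death day d in
    [min_death_day, max_death_day]; the cow returns to heat within one cycle
    of the death, so the implied bound (interval to next event minus cycle,
    and minus gestation for a calving) never exceeds d. Artifact classes are
    constructed disjoint: superovulation-flagged, an AI followed by another AI
    the next day, and all failures of low-fertility cows (>= 3 consecutive
    failures).
    """
    cfg.validate()
    records: list[AIRecord] = []
    cow_counter = 0

    def new_cow() -> str:
        nonlocal cow_counter
        cow_counter += 1
        return f"C{cow_counter:03d}"

    def clean_failure(cow: str, consec: int) -> AIRecord:
        ai_day = int(rng.integers(0, 365))
        d = int(rng.integers(cfg.min_death_day, cfg.max_death_day + 1))
        heat_delay = int(rng.integers(2, cfg.cycle_days + 1))  # > adjacent-AI gap
        if rng.random() < 0.5:
            return AIRecord(cow, ai_day, "failure", False, "ai",
                            ai_day + d + heat_delay, consec)
        return AIRecord(cow, ai_day, "failure", False, "calving",
                        ai_day + d + heat_delay + cfg.gestation_days, consec)

    n_clean = cfg.n_ai_failures - (
        cfg.n_superovulation_artifacts
        + cfg.n_adjacent_ai_artifacts
        + cfg.n_low_fertility_artifact_records
    )
    for _ in range(n_clean):
        records.append(clean_failure(new_cow(), int(rng.integers(1, 3))))
    for _ in range(cfg.n_superovulation_artifacts):
        ai_day = int(rng.integers(0, 365))
        records.append(
            AIRecord(new_cow(), ai_day, "failure", True, "ai", ai_day + 30, 1)
        )
    for _ in range(cfg.n_adjacent_ai_artifacts):
        ai_day = int(rng.integers(0, 365))
        records.append(
            AIRecord(new_cow(), ai_day, "failure", False, "ai", ai_day + 1, 1)
        )
    # low-fertility cows: partition the artifact records into runs of >= 3
    remaining = cfg.n_low_fertility_artifact_records
    while remaining > 0:
        # runs of 3 while possible, folding any short tail into the last run
        run = 3 if remaining >= 6 else remaining
        cow = new_cow()
        base_day = int(rng.integers(0, 200))
        for j in range(run):
            ai_day = base_day + j * 42
            records.append(
                AIRecord(cow, ai_day, "failure", False, "ai", ai_day + 42, max(run, 3))
            )
        remaining -= run
    for _ in range(cfg.n_ai_success):
        ai_day = int(rng.integers(0, 365))
        records.append(
            AIRecord(
                new_cow(), ai_day, "success", False, "calving",
                ai_day + cfg.gestation_days + int(rng.integers(-5, 6)), 1,
            )
        )
    return records


# ---------------------------------------------------------------------------
# full cohort


def simulate_cohort(cfg: SimulationConfig | None = None) -> CohortBundle:
    """Generate a complete, internally consistent cohort from one seed.

    Deterministic: the same config (seed included) yields an identical
    bundle. Component substreams are spawned in a fixed order so adding a
    component never perturbs the preceding ones.
    """
    cfg = cfg or SimulationConfig()
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    (ss_mark, ss_geno, ss_depth_c, ss_depth_n, ss_pairs, ss_counts, ss_ai) = ss.spawn(7)

    pedigree = build_pedigree(cfg)
    truth = Truth(
        chrom=cfg.chrom,
        left_flank=cfg.deletion_start_flank,
        right_flank=cfg.deletion_end_flank,
        inserted_seq=cfg.inserted_seq,
        germline_mosaicism=cfg.germline_mosaicism,
        male_lethality=cfg.male_lethality,
        max_death_day=cfg.max_death_day,
        carrier_ids=[r.animal_id for r in pedigree.records if r.phenotype == "affected"],
    )
    marker_map = build_marker_map(cfg, np.random.default_rng(ss_mark))
    genotypes = simulate_genotypes(
        pedigree, marker_map, truth, cfg, np.random.default_rng(ss_geno)
    )
    depth_carrier = simulate_depth(truth, cfg, True, np.random.default_rng(ss_depth_c))
    depth_control = simulate_depth(truth, cfg, False, np.random.default_rng(ss_depth_n))
    reference = SyntheticReference(cfg.seed, cfg.chrom, cfg.chrom_length)
    pairs = simulate_pairs(truth, cfg, np.random.default_rng(ss_pairs), reference)

    rng_counts = np.random.default_rng(ss_counts)
    sperm, experiments = simulate_sperm_counts(cfg, rng_counts)
    blasto = simulate_blastocyst_counts(cfg, rng_counts)
    birth = simulate_birth_counts(
        cfg.n_progeny_birth, cfg.germline_mosaicism, cfg.male_lethality, rng_counts
    )
    counts = {"sperm": sperm, "blastocyst": blasto, "birth": birth}

    ai_records = simulate_ai_records(cfg, np.random.default_rng(ss_ai))

    return CohortBundle(
        config=cfg,
        truth=truth,
        pedigree=pedigree,
        marker_map=marker_map,
        genotypes=genotypes,
        depth_carrier=depth_carrier,
        depth_control=depth_control,
        pairs=pairs,
        counts=counts,
        sperm_experiments=experiments,
        ai_records=ai_records,
        reference=reference,
    )
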