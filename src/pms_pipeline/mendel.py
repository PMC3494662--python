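"""Mendelian-error deletion mapping from SNP-array genotypes.

A hemizygous deletion transmitted from a sire shows up on an array as a
cluster of sire-offspring *opposite homozygotes*: the offspring is hemizygous
for the maternal allele, the array calls that as homozygous, and wherever the
sire is homozygous for the other allele the pair is Mendelianly impossible.
The same markers are depleted of heterozygous calls in carriers. This module
counts both signals per marker, clusters affected-only error markers into
candidate regions, and checks that affected calls inside a region are
consistent with pure maternal (hemizygous) inheritance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import (
    MISSING,
    GenotypeMatrix,
    MarkerMap,
    Pedigree,
    Region,
)


class NoInformativeMarkersError(ValueError):
    """A region contains no marker usable for the hemizygosity check."""


def opposite_homozygote_flags(
    sire_calls: np.ndarray, progeny_calls: np.ndarray
) -> np.ndarray:
    """Per-marker flags of Mendelianly impossible opposite homozygous pairs.

    True iff one call is 0 (AA) and the other 2 (BB); any no-call makes the
    pair uninformative (False).
    """
    s = np.asarray(sire_calls)
    p = np.asarray(progeny_calls)
    if s.shape != p.shape:
        raise ValueError(f"call vectors differ in length: {s.shape} vs {p.shape}")
    return ((s == 0) & (p == 2)) | ((s == 2) & (p == 0))


@dataclass
class MarkerErrorProfile:
    """Per-marker Mendelian-error and heterozygosity tallies.

    ``n_errors_affected`` / ``n_errors_unaffected``: sire-progeny opposite
    homozygote counts split by progeny phenotype; ``n_het_affected``: affected
    progeny called heterozygous; ``n_informative``: sire-progeny pairs with
    both calls present.
    """

    marker_ids: list[str]
    n_errors_affected: np.ndarray
    n_errors_unaffected: np.ndarray
    n_het_affected: np.ndarray
    n_informative: np.ndarray
    n_affected: int
    n_unaffected: int


def build_error_profile(
    gm: GenotypeMatrix, ped: Pedigree, sire_id: str
) -> MarkerErrorProfile:
    """Tally sire-progeny opposite homozygotes per marker, split by phenotype."""
    if sire_id not in gm.sample_ids:
        raise KeyError(f"sire {sire_id!r} not present in genotype matrix")
    sire = gm.row(sire_id)
    progeny = [r for r in ped.progeny_of(sire_id) if r.animal_id in gm.sample_ids]
    if not progeny:
        raise ValueError(f"no genotyped progeny of {sire_id!r}")
    n_mark = len(gm.marker_ids)
    err_aff = np.zeros(n_mark, dtype=np.int64)
    err_unaff = np.zeros(n_mark, dtype=np.int64)
    het_aff = np.zeros(n_mark, dtype=np.int64)
    informative = np.zeros(n_mark, dtype=np.int64)
    n_aff = n_unaff = 0
    for rec in progeny:
        calls = gm.row(rec.animal_id)
        flags = opposite_homozygote_flags(sire, calls)
        informative += ((sire != MISSING) & (calls != MISSING)).astype(np.int64)
        if rec.phenotype == "affected":
            n_aff += 1
            err_aff += flags
            het_aff += calls == 1
        else:
            n_unaff += 1
            err_unaff += flags
    return MarkerErrorProfile(
        marker_ids=list(gm.marker_ids),
        n_errors_affected=err_aff,
        n_errors_unaffected=err_unaff,
        n_het_affected=het_aff,
        n_informative=informative,
        n_affected=n_aff,
        n_unaffected=n_unaff,
    )


@dataclass(frozen=True)
class CandidateRegion:
    chrom: str
    start: int
    end: int
    n_error_markers: int
    n_het_markers_inside: int
    score: float

    def as_region(self) -> Region:
        return Region(self.chrom, self.start, self.end, "candidate")


def call_candidate_regions(
    profile: MarkerErrorProfile,
    marker_map: MarkerMap,
    *,
    min_affected_errors: int = 2,
    max_gap_bp: int = 1_000_000,
    min_cluster_size: int = 5,
    het_penalty: float = 1.0,
) -> list[CandidateRegion]:
    """Cluster affected-only error markers into ranked candidate regions.

    Seed markers carry >= *min_affected_errors* errors in affected progeny and
    none in unaffected progeny; seeds within *max_gap_bp* on the same
    chromosome merge; clusters with fewer than *min_cluster_size* seeds are
    dropped. Region bounds extend from the outermost seed markers to the
    midpoints toward the flanking non-seed markers. Score = seed count minus
    *het_penalty* times the number of in-region markers at which any affected
    animal is heterozygous; ties rank leftmost first.
    """
    if profile.marker_ids != marker_map.marker_ids:
        raise ValueError("profile and marker map are not aligned")
    t = marker_map.table
    pos = t["pos"].to_numpy()
    chroms = t["chrom"].to_numpy()
    seeds = (profile.n_errors_affected >= min_affected_errors) & (
        profile.n_errors_unaffected == 0
    )
    seed_idx = np.flatnonzero(seeds)
    if seed_idx.size == 0:
        return []

    clusters: list[list[int]] = []
    current = [int(seed_idx[0])]
    for idx in seed_idx[1:]:
        prev = current[-1]
        if chroms[idx] == chroms[prev] and pos[idx] - pos[prev] <= max_gap_bp:
            current.append(int(idx))
        else:
            clusters.append(current)
            current = [int(idx)]
    clusters.append(current)

    regions: list[CandidateRegion] = []
    for cl in clusters:
        if len(cl) < min_cluster_size:
            continue
        first, last = cl[0], cl[-1]
        chrom = chroms[first]
        # extend to midpoints toward the flanking markers on the same chromosome
        if first > 0 and chroms[first - 1] == chrom:
            start = (pos[first - 1] + pos[first]) // 2 + 1
        else:
            start = 1
        if last < len(pos) - 1 and chroms[last + 1] == chrom:
            end = (pos[last] + pos[last + 1]) // 2
        else:
            end = int(pos[last])
        inside = (chroms == chrom) & (pos >= start) & (pos <= end)
        n_het_inside = int(np.count_nonzero(inside & (profile.n_het_affected > 0)))
        score = float(len(cl) - het_penalty * n_het_inside)
        regions.append(
            CandidateRegion(str(chrom), int(start), int(end), len(cl), n_het_inside, score)
        )
    regions.sort(key=lambda r: (-r.score, r.chrom, r.start))
    return regions


def hemizygosity_consistency(
    region: Region,
    gm: GenotypeMatrix,
    ped: Pedigree,
    affected_ids: list[str],
    marker_map: MarkerMap,
) -> float:
    """Fraction of in-region affected calls consistent with hemizygosity.

    For each (affected animal, marker) pair inside *region* with both the
    animal and its dam called, the call is consistent iff it is homozygous
    for an allele the dam carries — i.e. explainable as the maternal allele
    alone after loss of the paternal copy. Heterozygous calls are
    inconsistent by definition.
    """
    t = marker_map.table
    pos = t["pos"].to_numpy()
    inside = (
        (t["chrom"].to_numpy() == region.chrom)
        & (pos >= region.start)
        & (pos <= region.end)
    )
    n_informative = 0
    n_consistent = 0
    for aid in affected_ids:
        rec = ped.get(aid)
        if rec.dam_id is None or rec.dam_id not in gm.sample_ids:
            continue
        a = gm.row(aid)[inside]
        d = gm.row(rec.dam_id)[inside]
        usable = (a != MISSING) & (d != MISSING)
        n_informative += int(usable.sum())
        au, du = a[usable], d[usable]
        # homozygous AA with dam carrying A, or BB with dam carrying B
        consistent = ((au == 0) & (du <= 1)) | ((au == 2) & (du >= 1))
        n_consistent += int(consistent.sum())
    if n_informative == 0:
        raise NoInformativeMarkersError(
            f"no informative marker in {region.chrom}:{region.start}-{region.end}"
        )
    return n_consistent / n_informative
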