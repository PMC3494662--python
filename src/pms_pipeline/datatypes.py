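"""Domain types shared across the pipeline.

Coordinates are 1-based inclusive throughout the package; BED input/output is
converted at the file boundary (see :mod:`pms_pipeline.io`). Genotype calls are
alt-allele (allele B) dosages in ``{0, 1, 2}`` with ``-1`` as the no-call
sentinel, the convention of array-genotype dosage matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

MISSING = -1
VALID_CALLS = frozenset({0, 1, 2, MISSING})

SEXES = ("M", "F", "U")
PHENOTYPES = ("affected", "unaffected", "unknown")

#: cell keys of a four-cell transmission table: (sex, carrier-status)
TRANSMISSION_CELLS = (("F", "wt"), ("F", "del"), ("M", "wt"), ("M", "del"))
STAGES = ("sperm", "blastocyst", "birth")


class SchemaError(ValueError):
    """A file or object violates its declared schema/invariants."""


@dataclass(frozen=True)
class MarkerMap:
    """SNP marker map: one biallelic marker per row, sorted by (chrom, pos)."""

    table: pd.DataFrame  # marker_id, chrom, pos, allele_a, allele_b, maf

    def __post_init__(self) -> None:
        t = self.table
        required = ["marker_id", "chrom", "pos", "allele_a", "allele_b", "maf"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise SchemaError(f"marker map missing columns: {missing}")
        if t["marker_id"].duplicated().any():
            dup = t.loc[t["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise SchemaError(f"duplicate marker_id {dup!r}")
        if (t["pos"] < 1).any():
            raise SchemaError("marker pos must be >= 1 (1-based)")
        if (t["allele_a"] == t["allele_b"]).any():
            raise SchemaError("allele_a must differ from allele_b")
        if ((t["maf"] < 0) | (t["maf"] > 0.5)).any():
            raise SchemaError("maf must lie in [0, 0.5]")
        key = t[["chrom", "pos"]]
        if not key.equals(key.sort_values(["chrom", "pos"]).reset_index(drop=True)):
            raise SchemaError("markers must be sorted by (chrom, pos)")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> list[str]:
        return self.table["marker_id"].tolist()

    @property
    def positions(self) -> np.ndarray:
        return self.table["pos"].to_numpy()


@dataclass
class GenotypeMatrix:
    """Sample x marker dosage calls (count of allele B; -1 = no-call)."""

    sample_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray  # int, shape (n_samples, n_markers)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise SchemaError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.marker_ids)} markers"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise SchemaError(
                f"illegal call {self.calls[i, j]} for sample "
                f"{self.sample_ids[i]!r} at marker {self.marker_ids[j]!r}"
            )

    def row(self, sample_id: str) -> np.ndarray:
        """Call vector for one sample; KeyError if absent."""
        try:
            idx = self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in genotype matrix") from None
        return self.calls[idx]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.calls, other.calls)
        )


@dataclass(frozen=True)
class PedigreeRecord:
    animal_id: str
    sire_id: str | None
    dam_id: str | None
    sex: str
    phenotype: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise SchemaError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.phenotype not in PHENOTYPES:
            raise SchemaError(
                f"phenotype must be one of {PHENOTYPES}, got {self.phenotype!r}"
            )


@dataclass
class Pedigree:
    records: list[PedigreeRecord]

    def __post_init__(self) -> None:
        ids = [r.animal_id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise SchemaError(f"duplicate animal_id {dup!r}")
        self._by_id = {r.animal_id: r for r in self.records}
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # DFS over parent links; a back-edge means an animal is its own ancestor
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(aid: str) -> None:
            if state.get(aid) == 1:
                return
            if state.get(aid) == 0:
                raise SchemaError(f"pedigree cycle involving {aid!r}")
            state[aid] = 0
            rec = self._by_id.get(aid)
            if rec is not None:
                for parent in (rec.sire_id, rec.dam_id):
                    if parent is not None and parent in self._by_id:
                        visit(parent)
            state[aid] = 1

        for rec in self.records:
            visit(rec.animal_id)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, animal_id: str) -> PedigreeRecord:
        return self._by_id[animal_id]

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self._by_id

    def progeny_of(self, sire_id: str) -> list[PedigreeRecord]:
        return [r for r in self.records if r.sire_id == sire_id]

    def affected_ids(self) -> list[str]:
        return [r.animal_id for r in self.records if r.phenotype == "affected"]


@dataclass
class DepthProfile:
    """Windowed read-depth track over one chromosome.

    ``windows`` has columns chrom, start, end (1-based inclusive), depth.
    """

    windows: pd.DataFrame
    genome_median_depth: float

    def __post_init__(self) -> None:
        w = self.windows
        required = ["chrom", "start", "end", "depth"]
        missing = [c for c in required if c not in w.columns]
        if missing:
            raise SchemaError(f"depth profile missing columns: {missing}")
        if (w["end"] < w["start"]).any():
            raise SchemaError("depth window with end < start")
        if (w["depth"] < 0).any():
            raise SchemaError("negative depth")
        for _, grp in w.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if not (np.diff(starts) > 0).all():
                raise SchemaError("depth windows not sorted by start")
            if (starts[1:] <= ends[:-1]).any():
                raise SchemaError("overlapping depth windows")
        if self.genome_median_depth < 0:
            raise SchemaError("genome_median_depth must be non-negative")


CLIP_SIDES = ("none", "left", "right")


@dataclass
class PairEvidence:
    """Read-pair and soft-clip evidence near a putative breakpoint.

    Columns: read_id, chrom, pos (1-based leftmost aligned base), mate_pos,
    insert (observed outer insert size), clip_side, clipped_seq.
    """

    table: pd.DataFrame
    read_len: int = 100

    def __post_init__(self) -> None:
        t = self.table
        required = [
            "read_id", "chrom", "pos", "mate_pos", "insert", "clip_side", "clipped_seq",
        ]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise SchemaError(f"pair evidence missing columns: {missing}")
        if not t["clip_side"].isin(CLIP_SIDES).all():
            raise SchemaError(f"clip_side must be one of {CLIP_SIDES}")
        paired = t["mate_pos"] > 0
        if (t.loc[paired, "insert"] <= 0).any():
            raise SchemaError("paired record with non-positive insert")
        has_clip = t["clipped_seq"].fillna("").astype(str) != ""
        if ((t["clip_side"] == "none") & has_clip).any():
            raise SchemaError("clipped_seq present with clip_side 'none'")
        if ((t["clip_side"] != "none") & ~has_clip).any():
            raise SchemaError("clip_side set but clipped_seq empty")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class TransmissionCounts:
    """Four-cell (sex x carrier) count table at one developmental stage."""

    stage: str
    counts: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise SchemaError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if set(self.counts) != set(TRANSMISSION_CELLS):
            raise SchemaError(
                f"counts must have exactly the cells {TRANSMISSION_CELLS}"
            )
        if any(v < 0 for v in self.counts.values()):
            raise SchemaError("negative transmission count")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_vector(self) -> np.ndarray:
        """Counts in the fixed cell order of TRANSMISSION_CELLS."""
        return np.array([self.counts[c] for c in TRANSMISSION_CELLS], dtype=float)

    @classmethod
    def from_vector(cls, stage: str, vec: Iterable[int]) -> "TransmissionCounts":
        vals = list(vec)
        return cls(stage, dict(zip(TRANSMISSION_CELLS, (int(v) for v in vals))))


NEXT_EVENTS = ("ai", "calving", "none")


@dataclass(frozen=True)
class AIRecord:
    """One artificial-insemination event with outcome and follow-up linkage."""

    cow_id: str
    ai_day: int
    outcome: str  # success | failure
    superovulation: bool
    next_event: str  # ai | calving | none
    next_event_day: int | None
    consecutive_failures_for_cow: int

    def __post_init__(self) -> None:
        if self.outcome not in ("success", "failure"):
            raise SchemaError(f"outcome must be success/failure, got {self.outcome!r}")
        if self.next_event not in NEXT_EVENTS:
            raise SchemaError(f"next_event must be one of {NEXT_EVENTS}")
        if self.next_event != "none" and self.next_event_day is None:
            raise SchemaError("next_event set but next_event_day absent")
        if self.next_event_day is not None and self.next_event_day <= self.ai_day:
            raise SchemaError(
                f"next_event_day {self.next_event_day} must exceed ai_day {self.ai_day}"
            )
        if self.consecutive_failures_for_cow < 1:
            raise SchemaError("consecutive_failures_for_cow must be >= 1")


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise SchemaError(f"region start {self.start} > end {self.end}")
        if self.start < 1:
            raise SchemaError("region start must be >= 1")

    def overlaps(self, other: "Region") -> bool:
        return self.chrom == other.chrom and (
            self.start <= other.end and other.start <= self.end
        )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class RegionSet:
    regions: list[Region] = field(default_factory=list)

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)


def bed_to_internal(start0: int, end0: int) -> tuple[int, int]:
    """Convert a BED (0-based half-open) interval to 1-based inclusive."""
    if end0 <= start0:
        raise SchemaError(f"empty/invalid BED interval [{start0}, {end0})")
    return start0 + 1, end0


def internal_to_bed(start1: int, end1: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to BED (0-based half-open)."""
    if end1 < start1:
        raise SchemaError(f"invalid interval ({start1}, {end1})")
    return start1 - 1, end1
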