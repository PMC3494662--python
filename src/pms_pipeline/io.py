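"""Readers and writers for the pipeline's on-disk formats.

All tabular files are plain TSV/CSV with a header row. Genotype files are
sample-major (one row per sample, one column per marker). Depth tracks use
1-based inclusive coordinates; BED files use the standard 0-based half-open
convention and are converted at this boundary.

Schema violations raise :class:`~pms_pipeline.datatypes.SchemaError` naming
the offending line where line-level attribution is possible.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    AIRecord,
    DepthProfile,
    GenotypeMatrix,
    MarkerMap,
    PairEvidence,
    Pedigree,
    PedigreeRecord,
    Region,
    RegionSet,
    SchemaError,
    TransmissionCounts,
    bed_to_internal,
    internal_to_bed,
)

PEDIGREE_MISSING_PARENT = "0"  # conventional pedigree-file sentinel


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(
    path: str | Path, marker_map: MarkerMap | None = None, *, strict: bool = True
) -> GenotypeMatrix:
    """Read a sample-major genotype TSV.

    With *strict* (default) any token outside {0, 1, 2, -1} is an error; in
    lenient mode unknown tokens become no-calls. If *marker_map* is given the
    header must list exactly its markers in order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise SchemaError(f"{path}: empty file")
        cols = header.split("\t")
        if cols[0] != "sample_id":
            raise SchemaError(f"{path}: first header column must be 'sample_id'")
        marker_ids = cols[1:]
        if marker_map is not None and marker_ids != marker_map.marker_ids:
            raise SchemaError(
                f"{path}: genotype header does not match marker map "
                f"({len(marker_ids)} vs {len(marker_map)} markers)"
            )
        sample_ids: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(marker_ids) + 1:
                raise SchemaError(
                    f"{path}:{lineno}: expected {len(marker_ids) + 1} fields, "
                    f"got {len(fields)}"
                )
            sample_ids.append(fields[0])
            row = np.empty(len(marker_ids), dtype=np.int8)
            for j, tok in enumerate(fields[1:]):
                if tok in ("0", "1", "2"):
                    row[j] = int(tok)
                elif tok == str(MISSING):
                    row[j] = MISSING
                elif strict:
                    raise SchemaError(
                        f"{path}:{lineno}: illegal call token {tok!r} "
                        f"(strict mode)"
                    )
                else:
                    row[j] = MISSING
            rows.append(row)
    calls = np.vstack(rows) if rows else np.empty((0, len(marker_ids)), dtype=np.int8)
    return GenotypeMatrix(sample_ids, marker_ids, calls)


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(gm.marker_ids) + "\n")
        for sid, row in zip(gm.sample_ids, gm.calls):
            fh.write(sid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# marker map


def read_marker_map(path: str | Path) -> MarkerMap:
    t = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "marker_id": str,
            "chrom": str,
            "pos": np.int64,
            "allele_a": str,
            "allele_b": str,
            "maf": float,
        },
    )
    return MarkerMap(t)


def write_marker_map(m: MarkerMap, path: str | Path) -> None:
    m.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pedigree


def read_pedigree(path: str | Path) -> Pedigree:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["animal_id", "sire_id", "dam_id", "sex", "phenotype"]
        if header != expected:
            raise SchemaError(f"{path}: pedigree header must be {expected}")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise SchemaError(f"{path}:{lineno}: expected 5 fields")
            animal, sire, dam, sex, pheno = fields
            try:
                records.append(
                    PedigreeRecord(
                        animal_id=animal,
                        sire_id=None if sire == PEDIGREE_MISSING_PARENT else sire,
                        dam_id=None if dam == PEDIGREE_MISSING_PARENT else dam,
                        sex=sex,
                        phenotype=pheno,
                    )
                )
            except SchemaError as e:
                raise SchemaError(f"{path}:{lineno}: {e}") from None
    return Pedigree(records)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("animal_id\tsire_id\tdam_id\tsex\tphenotype\n")
        for r in ped.records:
            fh.write(
                "\t".join(
                    [
                        r.animal_id,
                        r.sire_id or PEDIGREE_MISSING_PARENT,
                        r.dam_id or PEDIGREE_MISSING_PARENT,
                        r.sex,
                        r.phenotype,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# depth


def read_depth(path: str | Path) -> DepthProfile:
    t = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "depth": float},
    )
    required = ["chrom", "start", "end", "depth"]
    if list(t.columns) != required:
        raise SchemaError(f"{path}: depth header must be {required}")
    median = float(np.median(t["depth"])) if len(t) else 0.0
    return DepthProfile(t, genome_median_depth=median)


def write_depth(profile: DepthProfile, path: str | Path) -> None:
    profile.windows.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pair evidence


def read_pairs(path: str | Path, read_len: int = 100) -> PairEvidence:
    t = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "read_id": str,
            "chrom": str,
            "pos": np.int64,
            "mate_pos": np.int64,
            "insert": np.int64,
            "clip_side": str,
            "clipped_seq": str,
        },
        keep_default_na=False,
    )
    return PairEvidence(t, read_len=read_len)


def write_pairs(ev: PairEvidence, path: str | Path) -> None:
    ev.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# transmission counts


def read_counts(path: str | Path) -> dict[str, TransmissionCounts]:
    """Read a stage/sex/carrier/count TSV into per-stage tables."""
    t = pd.read_csv(path, sep="\t", dtype={"count": np.int64})
    required = ["stage", "sex", "carrier", "count"]
    if list(t.columns) != required:
        raise SchemaError(f"{path}: counts header must be {required}")
    out: dict[str, TransmissionCounts] = {}
    for stage, grp in t.groupby("stage", sort=False):
        counts = {
            (row.sex, row.carrier): int(row.count_)
            for row in grp.rename(columns={"count": "count_"}).itertuples()
        }
        out[str(stage)] = TransmissionCounts(str(stage), counts)
    return out


def write_counts(counts: dict[str, TransmissionCounts], path: str | Path) -> None:
    rows = []
    for stage in counts:
        for (sex, carrier), n in counts[stage].counts.items():
            rows.append((stage, sex, carrier, n))
    pd.DataFrame(rows, columns=["stage", "sex", "carrier", "count"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# AI records


def read_ai_records(path: str | Path) -> list[AIRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        expected = [
            "cow_id", "ai_day", "outcome", "superovulation",
            "next_event", "next_event_day", "consecutive_failures_for_cow",
        ]
        if header != expected:
            raise SchemaError(f"{path}: AI record header must be {expected}")
        for lineno, line in enumerate(fh, start=2):
            f = line.rstrip("\n").split(",")
            if len(f) != 7:
                raise SchemaError(f"{path}:{lineno}: expected 7 fields")
            try:
                records.append(
                    AIRecord(
                        cow_id=f[0],
                        ai_day=int(f[1]),
                        outcome=f[2],
                        superovulation=f[3].lower() in ("1", "true"),
                        next_event=f[4],
                        next_event_day=int(f[5]) if f[5] != "" else None,
                        consecutive_failures_for_cow=int(f[6]),
                    )
                )
            except (SchemaError, ValueError) as e:
                raise SchemaError(f"{path}:{lineno}: {e}") from None
    return records


def write_ai_records(records: list[AIRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "cow_id,ai_day,outcome,superovulation,"
            "next_event,next_event_day,consecutive_failures_for_cow\n"
        )
        for r in records:
            fh.write(
                f"{r.cow_id},{r.ai_day},{r.outcome},"
                f"{'true' if r.superovulation else 'false'},"
                f"{r.next_event},"
                f"{r.next_event_day if r.next_event_day is not None else ''},"
                f"{r.consecutive_failures_for_cow}\n"
            )


# ---------------------------------------------------------------------------
# BED regions


def read_bed(path: str | Path) -> RegionSet:
    """Read a BED file (0-based half-open) into internal 1-based regions."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise SchemaError(f"{path}:{lineno}: BED line needs >= 3 fields")
            try:
                start1, end1 = bed_to_internal(int(f[1]), int(f[2]))
            except (ValueError, SchemaError) as e:
                raise SchemaError(f"{path}:{lineno}: {e}") from None
            label = f[3] if len(f) > 3 else ""
            regions.append(Region(f[0], start1, end1, label))
    return RegionSet(regions)


def write_bed(rs: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in rs:
            s0, e0 = internal_to_bed(r.start, r.end)
            fields = [r.chrom, str(s0), str(e0)]
            if r.label:
                fields.append(r.label)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# JSON helper for reports / truth


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
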