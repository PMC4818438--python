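"""File formats, run configuration and report writers.

All tabular files are TSV with a header row, UTF-8, '.' decimal, and
1-based inclusive residue coordinates.  Report files carry no timestamps
so outputs diff cleanly; logging goes to standard error.

Formats
-------
domains TSV    protein_id, source_class, source_db, accession, start, end
tracks TSV     protein_id, position, feature_name, value   (long format)
labels TSV     protein_id, start, end        (positive / reference intervals)
masks TSV      protein_id, mask_kind, start, end
units TSV      protein_id, kind, start, end, length, mean_score, provenance
scores TSV     protein_id, position, score, masked
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .caller import CallerConfig, TargetScoreProfile, WeightVector
from .core import (
    DomainAnnotation,
    Interval,
    MaskKind,
    ProteinRecord,
    RegionMask,
    SourceClass,
    StructuredUnit,
    sanitize_sequence,
)
from .features import DEFAULT_WINDOWS, FeatureTrack, import_tracks
from .fixtures import FixtureDataset

logger = logging.getLogger("foldunits")


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(levelname)s %(name)s: %(message)s",
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Complete parameterization of one prediction run; YAML round-trips
    losslessly."""

    weights: WeightVector = WeightVector()
    caller: CallerConfig = CallerConfig()
    normalize_score: bool = True
    windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "weights": dataclasses.asdict(self.weights),
            "caller": dataclasses.asdict(self.caller),
            "normalize_score": self.normalize_score,
            "windows": dict(self.windows),
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(
            weights=WeightVector(**data.get("weights", {})),
            caller=CallerConfig(**data.get("caller", {})),
            normalize_score=bool(data.get("normalize_score", True)),
            windows=dict(data.get("windows", DEFAULT_WINDOWS)),
            log_level=str(data.get("log_level", "INFO")),
        )

    def write_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def read_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[ProteinRecord]:
    """Read protein records; id is the first header token, sequences are
    upper-cased (non-standard letters mapped to X)."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate protein id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, sanitize_sequence(str(rec.seq))))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_alignment_fasta(path) -> list[str]:
    """Aligned FASTA: returns the gapped rows, upper-cased."""
    rows = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise ValueError(f"no alignment rows found in {path}")
    return rows


_DOMAIN_COLUMNS = ["protein_id", "source_class", "source_db", "accession", "start", "end"]


def read_domains(path, proteins: dict[str, ProteinRecord]) -> dict[str, list[DomainAnnotation]]:
    """Read the domain annotation table; malformed rows and rows for
    unknown proteins are dropped with a warning."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(_DOMAIN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"domain TSV {path} lacks columns: {sorted(missing)}")

    out: dict[str, list[DomainAnnotation]] = {pid: [] for pid in proteins}
    for row in df.itertuples(index=False):
        pid = row.protein_id
        if pid not in proteins:
            logger.warning("domain row for unknown protein %s dropped", pid)
            continue
        try:
            start, end = int(row.start), int(row.end)
            iv = Interval(start, end)
            cls = SourceClass(row.source_class)
        except (ValueError, TypeError) as exc:
            logger.warning("malformed domain row %s dropped (%s)", tuple(row), exc)
            continue
        out[pid].append(
            DomainAnnotation(iv, cls, str(row.source_db), str(row.accession))
        )
    return out


def read_tracks(path, proteins: dict[str, ProteinRecord]) -> dict[str, dict[str, FeatureTrack]]:
    """Read the long-format per-residue track table (see module docstring)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"protein_id", "position", "feature_name", "value"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"track TSV {path} lacks columns: {sorted(missing)}")
    return import_tracks(df, proteins)


def read_intervals(path, kind_column: str | None = None) -> dict[str, list]:
    """Read a protein_id/start/end interval table (labels or reference
    regions); with ``kind_column``, rows carry (kind, Interval) tuples."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    needed = {"protein_id", "start", "end"} | ({kind_column} if kind_column else set())
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"interval TSV {path} lacks columns: {sorted(missing)}")
    out: dict[str, list] = {}
    for row in df.itertuples(index=False):
        iv = Interval(int(row.start), int(row.end))
        item = (getattr(row, kind_column), iv) if kind_column else iv
        out.setdefault(row.protein_id, []).append(item)
    return out


def read_masks(path) -> dict[str, list[RegionMask]]:
    """Mask TSV (protein_id, mask_kind, start, end) -> RegionMask lists."""
    raw = read_intervals(path, kind_column="mask_kind")
    out: dict[str, list[RegionMask]] = {}
    for pid, items in raw.items():
        by_kind: dict[MaskKind, list[Interval]] = {}
        for kind, iv in items:
            by_kind.setdefault(MaskKind(kind), []).append(iv)
        out[pid] = [
            RegionMask(kind, tuple(ivs)) for kind, ivs in sorted(by_kind.items())
        ]
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

_COORD_COMMENT = "# coordinates are 1-based, inclusive at both ends\n"


def write_fasta(proteins: list[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")


def write_domains(annotations: dict[str, list[DomainAnnotation]], path) -> None:
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT)
        fh.write("\t".join(_DOMAIN_COLUMNS) + "\n")
        for pid in annotations:
            for a in annotations[pid]:
                fh.write(
                    f"{pid}\t{a.source_class.value}\t{a.source_db}\t"
                    f"{a.accession}\t{a.interval.start}\t{a.interval.end}\n"
                )


def write_tracks(tracks: dict[str, dict[str, FeatureTrack]], path) -> None:
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT)
        fh.write("protein_id\tposition\tfeature_name\tvalue\n")
        for pid in tracks:
            for name in sorted(tracks[pid]):
                for pos, val in enumerate(tracks[pid][name].values, start=1):
                    fh.write(f"{pid}\t{pos}\t{name}\t{val:.6f}\n")


def write_intervals(intervals: dict[str, list[Interval]], path) -> None:
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT)
        fh.write("protein_id\tstart\tend\n")
        for pid in intervals:
            for iv in intervals[pid]:
                fh.write(f"{pid}\t{iv.start}\t{iv.end}\n")


def write_dataset(dataset: FixtureDataset, outdir) -> dict[str, Path]:
    """Write a synthetic dataset as proteins.fasta, domains.tsv,
    tracks.tsv and labels.tsv under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "proteins.fasta",
        "domains": outdir / "domains.tsv",
        "tracks": outdir / "tracks.tsv",
        "labels": outdir / "labels.tsv",
    }
    write_fasta(dataset.proteins, paths["fasta"])
    write_domains(dataset.annotations, paths["domains"])
    write_tracks(dataset.tracks, paths["tracks"])
    write_intervals(dataset.labels, paths["labels"])
    return paths


def write_report(
    units: dict[str, list[StructuredUnit]],
    profiles: dict[str, TargetScoreProfile],
    path_prefix,
    config: RunConfig | None = None,
) -> dict[str, Path]:
    """Write the three report files for one run.

    ``<prefix>.units.tsv`` — one row per structured unit;
    ``<prefix>.scores.tsv`` — per-residue target score and mask flag;
    ``<prefix>.summary.json`` — config echo plus unit counts.
    Rows are ordered by protein (input order) then start coordinate.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    units_path = prefix.with_suffix(".units.tsv")
    scores_path = prefix.with_suffix(".scores.tsv")
    summary_path = prefix.with_suffix(".summary.json")

    with open(units_path, "w") as fh:
        fh.write(_COORD_COMMENT)
        fh.write("protein_id\tkind\tstart\tend\tlength\tmean_score\tprovenance\n")
        for pid in units:
            for u in sorted(units[pid], key=lambda u: u.interval):
                fh.write(
                    f"{pid}\t{u.kind.value}\t{u.interval.start}\t{u.interval.end}"
                    f"\t{u.interval.length}\t{u.mean_score:.4f}\t{u.provenance}\n"
                )

    with open(scores_path, "w") as fh:
        fh.write(_COORD_COMMENT)
        fh.write("protein_id\tposition\tscore\tmasked\n")
        for pid, profile in profiles.items():
            for pos in range(len(profile)):
                fh.write(
                    f"{pid}\t{pos + 1}\t{profile.scores[pos]:.4f}"
                    f"\t{int(profile.masked[pos])}\n"
                )

    n_domains = sum(
        sum(u.kind.value == "consensus_domain" for u in us) for us in units.values()
    )
    n_putative = sum(
        sum(u.kind.value == "putative_unit" for u in us) for us in units.values()
    )
    summary = {
        "n_proteins": len(units),
        "n_consensus_domains": n_domains,
        "n_putative_units": n_putative,
        "config": (config or RunConfig()).to_dict(),
    }
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return {"units": units_path, "scores": scores_path, "summary": summary_path}


def read_units(path) -> dict[str, list[StructuredUnit]]:
    """Round-trip reader for the units report TSV."""
    from .core import UnitKind

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    out: dict[str, list[StructuredUnit]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.protein_id, []).append(
            StructuredUnit(
                Interval(int(row.start), int(row.end)),
                UnitKind(row.kind),
                mean_score=float(row.mean_score),
                provenance=str(row.provenance),
            )
        )
    return out
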