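"""File dialects, dataset schemas, checkpoints and manifests.

Formats: FASTA for genomes, BED3+ for peak tracks, bedGraph for RRBS
methylation betas (track files follow the ``<cell_type>.<mark>.bed`` /
``.bedgraph`` naming convention), tab-separated tables for labeled
on-target and detection data, BED6+ for candidate exports, and ``.npz``
checkpoints that carry the architecture config, seed and a data-schema
hash so a model can never silently score inputs encoded under a different
channel order.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

from .encoder import CHANNELS, GUIDE_LEN, GuideSequence
from .offtarget import OffTargetCandidate
from .ontarget import OnTargetRecord

__all__ = [
    "read_fasta", "write_fasta",
    "read_tracks", "read_bed", "read_bedgraph", "write_tracks",
    "read_ontarget_tsv", "write_ontarget_tsv",
    "read_detections_tsv", "write_candidates_bed",
    "save_checkpoint", "load_checkpoint", "schema_hash",
    "DatasetManifest", "write_manifest", "read_manifest",
]

SCHEMA_VERSION = "1"

ONTARGET_COLUMNS = ["chrom", "start", "end", "strand", "sequence23",
                    "cell_type", "experiment_id", "raw_efficacy",
                    "binary_label", "normalized_label"]
DETECTION_COLUMNS = ["guide_id", "chrom", "start", "strand", "assay",
                     "indel_frequency"]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Named sequence map, uppercased, line-wrap agnostic."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    _ = width  # Biopython wraps at 60; wrap width is cosmetic


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

def _read_intervals(path, n_cols: int) -> pd.DataFrame:
    names = ["chrom", "start", "end", "value"][:n_cols]
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=range(n_cols), names=names)
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        raise ValueError(
            f"{path}: end <= start at line {int(bad[0]) + 1}")
    return df


def read_bed(path) -> pd.DataFrame:
    """BED3+ peak intervals, 0-based half-open."""
    return _read_intervals(path, 3)


def read_bedgraph(path) -> pd.DataFrame:
    """bedGraph intervals with a real value column."""
    return _read_intervals(path, 4)


def _to_trees(df: pd.DataFrame, with_value: bool) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in df.groupby("chrom"):
        tree = IntervalTree()
        for row in sub.itertuples(index=False):
            tree.addi(row.start, row.end,
                      float(row.value) if with_value else None)
        trees[str(chrom)] = tree
    return trees


def read_tracks(paths) -> dict[tuple[str, str], dict[str, IntervalTree]]:
    """Load track files named ``<cell_type>.<mark>.bed|bedgraph``.

    Returns ``{(cell_type, mark): {chrom: IntervalTree}}``; rrbs interval
    data carry the methylation beta, peak intervals carry None.
    """
    out: dict[tuple[str, str], dict[str, IntervalTree]] = {}
    for path in map(Path, paths):
        parts = path.name.split(".")
        if len(parts) < 3:
            raise ValueError(
                f"track file {path.name!r} does not follow "
                "<cell_type>.<mark>.bed|bedgraph")
        cell_type, mark, ext = parts[0], parts[1].lower(), parts[-1].lower()
        if ext == "bedgraph":
            out[(cell_type, mark)] = _to_trees(read_bedgraph(path), True)
        else:
            out[(cell_type, mark)] = _to_trees(read_bed(path), False)
    return out


def tracks_for_cell_type(tracks: dict, cell_type: str) -> dict:
    """Slice a read_tracks() result down to {mark: trees} for one cell type."""
    return {mark: trees for (ct, mark), trees in tracks.items()
            if ct == cell_type}


def write_tracks(tracks: dict[str, pd.DataFrame], outdir, cell_type: str
                 ) -> list[Path]:
    """Write synthetic track frames under the naming convention."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for mark, df in tracks.items():
        ext = "bedgraph" if "value" in df.columns else "bed"
        path = outdir / f"{cell_type}.{mark}.{ext}"
        df.to_csv(path, sep="\t", header=False, index=False)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Labeled tables
# ---------------------------------------------------------------------------

def write_ontarget_tsv(records: list[OnTargetRecord], path) -> None:
    rows = []
    for r in records:
        rows.append({
            "chrom": r.guide.chrom, "start": r.guide.start, "end": r.guide.end,
            "strand": r.guide.strand, "sequence23": r.guide.sequence,
            "cell_type": r.cell_type, "experiment_id": r.experiment_id,
            "raw_efficacy": r.raw_efficacy,
            "binary_label": "" if r.binary_label is None else r.binary_label,
            "normalized_label": ("" if r.normalized_label is None
                                 else r.normalized_label),
        })
    pd.DataFrame(rows, columns=ONTARGET_COLUMNS).to_csv(
        path, sep="\t", index=False)


def read_ontarget_tsv(path) -> list[OnTargetRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(ONTARGET_COLUMNS[:8]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        binary = getattr(row, "binary_label", None)
        norm = getattr(row, "normalized_label", None)
        records.append(OnTargetRecord(
            guide=GuideSequence(row.sequence23, row.chrom, int(row.start),
                                int(row.end), row.strand, str(row.cell_type)),
            experiment_id=str(row.experiment_id), cell_type=str(row.cell_type),
            raw_efficacy=float(row.raw_efficacy),
            binary_label=None if pd.isna(binary) else int(binary),
            normalized_label=None if pd.isna(norm) else float(norm)))
    return records


def read_detections_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DETECTION_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return df


def write_candidates_bed(guide_id: str, candidates: list[OffTargetCandidate],
                         path) -> None:
    """BED6+ export: name=guide_id, score=mismatch count, plus sequence
    and the mismatch-profile string (e.g. ``16:G>C;18:A>T``)."""
    rows = []
    for c in candidates:
        rows.append([c.site.chrom, c.site.start, c.site.end, guide_id,
                     c.mismatch_count, c.site.strand, c.site.sequence23,
                     c.profile_string()])
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def schema_hash() -> str:
    """Hash of the encoding contract a checkpoint was trained under."""
    text = ",".join(CHANNELS) + f"|L={GUIDE_LEN}|v={SCHEMA_VERSION}"
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def save_checkpoint(model, path) -> None:
    state = model.to_state()
    header = json.dumps({
        "kind": state["kind"], "config": state["config"],
        "schema_hash": schema_hash(), "schema_version": SCHEMA_VERSION,
        "parts": {k: len(v) for k, v in state["parts"].items()},
        "member_kinds": state.get("member_kinds"),
    })
    arrays = {}
    for part, arrs in state["parts"].items():
        for i, a in enumerate(arrs):
            arrays[f"{part}__{i}"] = a
    np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path):
    from .nets import EnsembleModel, OffTargetModel, OnTargetModel, ParentEncoder
    try:
        data = np.load(path)
        header = json.loads(bytes(data["__header__"]).decode())
    except Exception as exc:
        raise ValueError(f"unreadable or truncated checkpoint {path}: {exc}")
    if header["schema_hash"] != schema_hash():
        raise ValueError(
            f"checkpoint {path} was written under data-schema hash "
            f"{header['schema_hash']}, current is {schema_hash()}")
    parts = {part: [data[f"{part}__{i}"] for i in range(n)]
             for part, n in header["parts"].items()}
    state = {"kind": header["kind"], "config": header["config"], "parts": parts,
             "member_kinds": header.get("member_kinds")}
    cls = {"ontarget": OnTargetModel, "offtarget": OffTargetModel,
           "parent": ParentEncoder, "ensemble": EnsembleModel}[header["kind"]]
    return cls.from_state(state)


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def _file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class DatasetManifest(dict):
    """JSON manifest recording files, row counts, seed and checksums."""


def write_manifest(path, files: dict[str, Path], seed: int,
                   config: dict | None = None,
                   row_counts: dict[str, int] | None = None) -> DatasetManifest:
    manifest = DatasetManifest(
        schema_version=SCHEMA_VERSION, seed=seed, config=config or {},
        files={name: {"path": str(p), "checksum": _file_checksum(p),
                      "rows": (row_counts or {}).get(name)}
               for name, p in files.items()})
    Path(path).write_text(json.dumps(manifest, indent=2))
    return manifest


def read_manifest(path, verify: bool = True) -> DatasetManifest:
    manifest = DatasetManifest(json.loads(Path(path).read_text()))
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"unrecognized manifest schema {manifest.get('schema_version')!r}")
    if verify:
        for name, info in manifest["files"].items():
            actual = _file_checksum(info["path"])
            if actual != info["checksum"]:
                raise ValueError(
                    f"checksum mismatch for {name}: {actual} != {info['checksum']}")
    return manifest
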