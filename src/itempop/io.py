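"""File readers/writers tying the pipeline stages together.

Conventions: FASTA for proteins and Tregitope registries (CSV alternative
``id,peptide``); CSV dialects defined per stage with a header row and stable
column order; percentages 0-100 in files, fractions internally; 1-based
inclusive coordinates in all per-frame and per-span outputs.
"""

from __future__ import annotations

import csv
import datetime
import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scanning import (
    HIT_CLASS_CODES,
    AssessmentGrid,
    ProteinRecord,
    ScoreReport,
    TregitopeRegistry,
)


def read_proteins_fasta(path: str | Path) -> list[ProteinRecord]:
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def write_proteins_fasta(proteins: Sequence[ProteinRecord], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in proteins
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_registry(path: str | Path) -> TregitopeRegistry:
    """Tregitope registry from FASTA, or CSV with columns id,peptide."""
    path = Path(path)
    if path.suffix.lower() in {".fa", ".fasta", ".faa"}:
        entries = [
            (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
        ]
    else:
        with open(path, newline="") as fh:
            entries = [
                (rec["id"], rec["peptide"].upper()) for rec in csv.DictReader(fh)
            ]
    return TregitopeRegistry(entries=entries)


def write_registry_fasta(registry: TregitopeRegistry, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(pep), id=tid, description="") for tid, pep in registry.entries
    ]
    SeqIO.write(recs, str(path), "fasta")


def grid_to_frame(grid: AssessmentGrid) -> pd.DataFrame:
    """Long-format view of a grid: one row per (frame, allele) assessment."""
    rows = []
    for i, frame in enumerate(grid.frames):
        for j, allele in enumerate(grid.alleles):
            rows.append(
                {
                    "protein": grid.protein_id,
                    "frame_start": int(frame),
                    "allele": allele,
                    "z": float(grid.z[i, j]),
                    "class": HIT_CLASS_CODES[int(grid.hit_class[i, j])],
                    "masked": bool(grid.masked[i]),
                }
            )
    return pd.DataFrame(
        rows, columns=["protein", "frame_start", "allele", "z", "class", "masked"]
    )


def write_grids_csv(grids: Sequence[AssessmentGrid], path: str | Path) -> None:
    pd.concat([grid_to_frame(g) for g in grids], ignore_index=True).to_csv(
        path, index=False
    )


def reports_to_frame(
    reports: Sequence[ScoreReport], lengths: dict[str, int]
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein": r.protein_id,
                "length": lengths[r.protein_id],
                "assessments": r.assessments,
                "raw_score": r.raw_score,
                "adjusted_score": r.adjusted_score,
            }
            for r in reports
        ],
        columns=["protein", "length", "assessments", "raw_score", "adjusted_score"],
    )


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    config: dict,
    inputs: Iterable[str | Path],
    seed: int | None,
) -> Path:
    """Run manifest: config snapshot, input checksums, seed, version, time.

    Written once per run; sufficient (with the inputs) to reproduce the run.
    The timestamp is the only non-deterministic field, so byte-level
    reproducibility checks should compare the stage outputs, not the
    manifest.
    """
    from . import __version__

    out_dir = Path(out_dir)
    manifest = {
        "tool": "itempop",
        "version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {
            str(p): sha256_of(p) for p in inputs if Path(p).is_file()
        },
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
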