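"""Reading and writing the pipeline's on-disk formats.

FASTA for sequences (via Biopython), TSV for pair lists and localization
tables (via pandas), JSON for manifests.  All writers are deterministic so
reruns with identical seeds produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dataset import InteractionPair, ProteinRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_pairs_tsv",
    "write_pairs_tsv",
    "read_localization_tsv",
    "write_localization_tsv",
    "write_json",
    "read_json",
    "file_digest",
]

PAIR_COLUMNS = ["protein_id_a", "protein_id_b", "label", "provenance"]


def read_fasta(
    path: str | Path,
    localization: Mapping[str, FrozenSet[str]] | None = None,
) -> List[ProteinRecord]:
    """Load protein records from FASTA (single-line or wrapped)."""
    localization = localization or {}
    return [
        ProteinRecord(
            id=rec.id,
            sequence=str(rec.seq).upper(),
            localization=localization.get(rec.id, frozenset()),
        )
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_pairs_tsv(path: str | Path) -> List[InteractionPair]:
    """Load a pair list; label defaults to 1 and provenance to 'positive'."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "label" not in df.columns:
        df["label"] = "1"
    if "provenance" not in df.columns:
        df["provenance"] = "positive"
    return [
        InteractionPair(
            id_a=row.protein_id_a,
            id_b=row.protein_id_b,
            label=int(row.label),
            provenance=row.provenance,
        )
        for row in df.itertuples()
    ]


def write_pairs_tsv(pairs: Iterable[InteractionPair], path: str | Path) -> None:
    df = pd.DataFrame(
        [(p.id_a, p.id_b, p.label, p.provenance) for p in pairs],
        columns=PAIR_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_localization_tsv(path: str | Path) -> Dict[str, FrozenSet[str]]:
    """Load per-protein localization terms (semicolon-separated column)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return {
        row.protein_id: frozenset(t for t in row.terms.split(";") if t)
        for row in df.itertuples()
    }


def write_localization_tsv(
    table: Mapping[str, FrozenSet[str]], path: str | Path
) -> None:
    df = pd.DataFrame(
        [(pid, ";".join(sorted(terms))) for pid, terms in sorted(table.items())],
        columns=["protein_id", "terms"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_json(obj: object, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def file_digest(path: str | Path) -> str:
    """SHA-256 hex digest of a file, for run manifests."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
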