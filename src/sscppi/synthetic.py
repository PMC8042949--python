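"""Synthetic interactomes with planted, sequence-determined interaction structure.

The generator emulates the premise that interaction is decided by sequence
content: a library of motif pairs (motif_a, motif_b) is planted into
otherwise i.i.d.-uniform random sequences, and a pair of proteins interacts
iff some library entry has motif_a in one sequence and motif_b in the other.
Because the signal is motif *co-occurrence* rather than whole-sequence
similarity, the statistics (S2) and context (C) channels carry exploitable
information beyond raw residue identity — the same logic the channel
ablation probes, at desk scale.

Proteins also receive random localization terms so the location-disjoint
negative sampler can be exercised.  Everything is driven by one seed;
regenerating with the same seed reproduces byte-identical FASTA/TSV files.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Sequence, Tuple

import numpy as np

from .dataset import InteractionPair, ProteinRecord, pair_key
from .encoding import STANDARD_RESIDUES
from . import io

__all__ = [
    "SyntheticConfig",
    "generate_interactome",
    "write_interactome",
    "make_fixture_suite",
    "CNKR1_PREFIX",
]

#: First twenty residues of the human CNKR1 protein — the worked example for
#: the context-channel asymmetry (its M-E bigram codes 0.5075 forward and
#: 0.1750 reversed).
CNKR1_PREFIX = "MEPVETWTPGKVATWLRGLD"

#: Default planted motif pairs: distinctive 6-mers, well below the minimum
#: sequence length, chosen with varied residue composition.
DEFAULT_MOTIF_LIBRARY = (
    ("WCMHYK", "DDGWFP"),
    ("QHWKCY", "NFPMDG"),
    ("KYHCWM", "GPDFNW"),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of a generated interactome.

    Defaults give 160 proteins of 30-120 residues with three planted motif
    pairs, enough to yield on the order of a thousand interacting pairs
    (hence ~1,600 train / 400 test after balancing and splitting) — a
    desk-scale stand-in for a curated PPI database.
    """

    n_proteins: int = 160
    length_range: Tuple[int, int] = (30, 120)
    motif_library: Tuple[Tuple[str, str], ...] = DEFAULT_MOTIF_LIBRARY
    motif_plant_prob: float = 0.7
    label_noise: float = 0.0
    localization_terms: Tuple[str, ...] = (
        "nucleus",
        "cytosol",
        "membrane",
        "mitochondrion",
        "secreted",
        "er",
    )
    max_terms_per_protein: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (20 <= lo <= hi <= 1800):
            raise ValueError("length_range must lie within [20, 1800]")
        for ma, mb in self.motif_library:
            if max(len(ma), len(mb)) >= lo:
                raise ValueError(
                    f"motif pair ({ma!r}, {mb!r}) is not shorter than the "
                    f"minimum sequence length {lo}"
                )
            for m in (ma, mb):
                if any(r not in STANDARD_RESIDUES for r in m):
                    raise ValueError(f"motif {m!r} contains nonstandard residues")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")


def _interacts(seq_a: str, seq_b: str, library: Sequence[Tuple[str, str]]) -> bool:
    """The planted rule: some (motif_a, motif_b) spans the pair, either way round."""
    return any(
        (ma in seq_a and mb in seq_b) or (ma in seq_b and mb in seq_a)
        for ma, mb in library
    )


def generate_interactome(
    config: SyntheticConfig,
) -> Tuple[List[ProteinRecord], List[InteractionPair], Dict[str, FrozenSet[str]]]:
    """Generate proteins, interacting pairs, and a localization table.

    Sequences are i.i.d. uniform over the 20-letter alphabet; with
    probability ``motif_plant_prob`` a protein receives one motif (a random
    side of a random library entry) written over a random position.  The
    positive list contains every pair satisfying the motif rule, with each
    pair's evaluation flipped independently with probability ``label_noise``.
    """
    rng = np.random.default_rng(config.seed)
    residues = np.array(list(STANDARD_RESIDUES))
    lo, hi = config.length_range
    flat_motifs = [m for pair in config.motif_library for m in pair]
    records: List[ProteinRecord] = []
    loc_table: Dict[str, FrozenSet[str]] = {}
    width = len(str(config.n_proteins - 1)) if config.n_proteins else 1
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(residues, size=length))
        if flat_motifs and rng.random() < config.motif_plant_prob:
            motif = flat_motifs[int(rng.integers(0, len(flat_motifs)))]
            start = int(rng.integers(0, length - len(motif) + 1))
            seq[start : start + len(motif)] = list(motif)
        n_terms = int(rng.integers(1, config.max_terms_per_protein + 1))
        term_idx = rng.choice(
            len(config.localization_terms), size=n_terms, replace=False
        )
        pid = f"SYN{i:0{width}d}"
        loc = frozenset(config.localization_terms[t] for t in sorted(term_idx))
        records.append(ProteinRecord(id=pid, sequence="".join(seq), localization=loc))
        loc_table[pid] = loc
    positives: List[InteractionPair] = []
    for a, b in itertools.combinations(records, 2):
        hit = _interacts(a.sequence, b.sequence, config.motif_library)
        if config.label_noise > 0.0 and rng.random() < config.label_noise:
            hit = not hit
        if hit:
            positives.append(InteractionPair(a.id, b.id, 1, "positive"))
    return records, positives, loc_table


def write_interactome(
    out_dir: str | Path,
    records: Sequence[ProteinRecord],
    positives: Sequence[InteractionPair],
    loc_table: Dict[str, FrozenSet[str]],
) -> Dict[str, Path]:
    """Write proteins.fasta, positives.tsv and localization.tsv into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "proteins.fasta",
        "pairs": out / "positives.tsv",
        "localization": out / "localization.tsv",
    }
    io.write_fasta(records, paths["fasta"])
    io.write_pairs_tsv(positives, paths["pairs"])
    io.write_localization_tsv(loc_table, paths["localization"])
    return paths


def make_fixture_suite(seed: int = 0) -> Dict[str, object]:
    """Small canonical fixtures for exercising every pipeline edge.

    Includes the CNKR1 20-residue prefix (the worked context-channel
    example), boundary-length sequences at 19/20/1800/1801 residues, a
    palindromic sequence, an all-'A' homopolymer (the one sequence whose
    context channel survives a pair swap exactly, because every A-A bigram
    codes to 0) and a non-palindromic partner.
    """
    rng = np.random.default_rng(seed)
    residues = np.array(list(STANDARD_RESIDUES))

    def random_seq(n: int) -> str:
        return "".join(rng.choice(residues, size=n))

    palindrome_half = random_seq(10)
    palindrome = palindrome_half + palindrome_half[::-1]
    return {
        "cnkr1_prefix": CNKR1_PREFIX,
        "boundary_records": [
            ProteinRecord("len19", random_seq(19)),
            ProteinRecord("len20", random_seq(20)),
            ProteinRecord("len1800", random_seq(1800)),
            ProteinRecord("len1801", random_seq(1801)),
        ],
        "palindrome": ProteinRecord("palin", palindrome),
        "homopolymer_a": ProteinRecord("polyA", "A" * 20),
        "non_palindrome": ProteinRecord("nonpalin", CNKR1_PREFIX),
        "random_pair": (
            ProteinRecord("rndA", random_seq(40)),
            ProteinRecord("rndB", random_seq(55)),
        ),
    }
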