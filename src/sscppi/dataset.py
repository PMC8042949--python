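"""Labeled PPI dataset construction.

Covers the preprocessing pipeline around the encoder: the 20..1800 residue
length filter, redundancy reduction at 60% global identity (a greedy
longest-first stand-in for CD-HIT clustering), three negative-sampling
strategies (random non-recorded pairs, localization-disjoint pairs, and
positives with 20-80% of one partner's residues substituted), the
interaction-degree threshold filter, and stratified 80/20 + k-fold splits.

Pairs are unordered for sampling and degree bookkeeping (the canonical key
sorts the two ids); the encoder consumes the ordered (a, b) as given.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set, Tuple

import edlib
import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .encoding import AminoAcidAlphabet, DEFAULT_ALPHABET

__all__ = [
    "ProteinRecord",
    "InteractionPair",
    "DatasetSplit",
    "filter_proteins",
    "global_identity",
    "reduce_redundancy",
    "sample_random_negatives",
    "sample_location_negatives",
    "sample_edited_negatives",
    "assemble_negatives",
    "degree_threshold_filter",
    "make_splits",
    "pair_key",
]

#: Negative-strategy mix, as fractions of the requested total.  Mirrors the
#: published composition 70,000 location + 70,000 edited out of 260,639
#: negatives, with random pairs making up the remainder.
DEFAULT_NEGATIVE_MIX = {
    "location_neg": 70_000 / 260_639,
    "edited_neg": 70_000 / 260_639,
    "random_neg": 120_639 / 260_639,
}

PROVENANCES = ("positive", "random_neg", "location_neg", "edited_neg")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein: accession id, residue string, optional localization terms."""

    id: str
    sequence: str
    localization: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        object.__setattr__(self, "localization", frozenset(self.localization))


@dataclass(frozen=True)
class InteractionPair:
    """An (ordered as given) protein pair with binary label and provenance."""

    id_a: str
    id_b: str
    label: int
    provenance: str = "positive"

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def key(self) -> Tuple[str, str]:
        return pair_key(self.id_a, self.id_b)


@dataclass
class DatasetSplit:
    """Stratified train/test split plus k cross-validation folds of the train set."""

    train: List[InteractionPair]
    test: List[InteractionPair]
    folds: List[List[InteractionPair]]
    seed: int


def pair_key(id_a: str, id_b: str) -> Tuple[str, str]:
    """Canonical unordered key of a pair."""
    return (id_a, id_b) if id_a <= id_b else (id_b, id_a)


def filter_proteins(
    records: Iterable[ProteinRecord],
    min_len: int = 20,
    max_len: int = 1800,
    alphabet: AminoAcidAlphabet = DEFAULT_ALPHABET,
    nonstandard_policy: str = "reject",
) -> Tuple[List[ProteinRecord], List[Tuple[str, str]]]:
    """Length/residue filter.  Returns (kept, rejection log).

    Boundary lengths are inclusive: 20 and 1800 survive, 19 and 1801 do not.
    Under the ``reject`` policy a sequence containing any residue outside the
    20-letter alphabet is dropped with reason "nonstandard residue".
    """
    kept: List[ProteinRecord] = []
    log: List[Tuple[str, str]] = []
    for rec in records:
        n = len(rec.sequence)
        if n < min_len:
            log.append((rec.id, f"too short ({n} < {min_len})"))
        elif n > max_len:
            log.append((rec.id, f"too long ({n} > {max_len})"))
        elif nonstandard_policy == "reject" and any(
            r not in alphabet for r in rec.sequence
        ):
            log.append((rec.id, "nonstandard residue"))
        else:
            kept.append(rec)
    return kept, log


def global_identity(seq_a: str, seq_b: str) -> float:
    """Global pairwise identity estimate: 1 - edit_distance / max(len)."""
    dist = edlib.align(seq_a, seq_b, mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / max(len(seq_a), len(seq_b))


def reduce_redundancy(
    records: Sequence[ProteinRecord], identity_threshold: float = 0.60
) -> List[ProteinRecord]:
    """Greedy longest-first redundancy reduction.

    Records are visited sorted by length descending then id; a record is
    dropped if its global identity to any already-kept representative
    exceeds the threshold.  Deterministic for a given input set.
    """
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    kept: List[ProteinRecord] = []
    for rec in ordered:
        if all(
            global_identity(rec.sequence, rep.sequence) <= identity_threshold
            for rep in kept
        ):
            kept.append(rec)
    return kept


def _positive_keys(positives: Iterable[InteractionPair]) -> Set[Tuple[str, str]]:
    return {p.key for p in positives}


def sample_random_negatives(
    positives: Iterable[InteractionPair],
    proteins: Sequence[ProteinRecord],
    n: int,
    seed: int = 0,
) -> List[InteractionPair]:
    """Draw n unordered pairs with no recorded interaction, label 0.

    Sampling is uniform without replacement over the complement of the
    positive set; raises if fewer than n such pairs exist.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    ids = sorted(r.id for r in proteins)
    pos = _positive_keys(positives)
    ids_set = set(ids)
    n_total = len(ids) * (len(ids) - 1) // 2
    n_pos_in_universe = sum(1 for k in pos if k[0] in ids_set and k[1] in ids_set)
    available = n_total - n_pos_in_universe
    if n > available:
        raise ValueError(
            f"requested {n} random negatives but only {available} "
            f"non-recorded pairs exist"
        )
    if n == 0:
        return []
    if n_total <= 2_000_000:
        complement = [
            k for k in itertools.combinations(ids, 2) if k not in pos
        ]
        chosen_idx = rng.choice(len(complement), size=n, replace=False)
        chosen = [complement[i] for i in sorted(chosen_idx)]
    else:  # rejection sampling for large universes
        chosen_set: Set[Tuple[str, str]] = set()
        while len(chosen_set) < n:
            i, j = rng.integers(0, len(ids), size=2)
            if i == j:
                continue
            k = pair_key(ids[i], ids[j])
            if k not in pos and k not in chosen_set:
                chosen_set.add(k)
        chosen = sorted(chosen_set)
    return [InteractionPair(a, b, 0, "random_neg") for a, b in chosen]


def sample_location_negatives(
    proteins: Sequence[ProteinRecord],
    positives: Iterable[InteractionPair],
    n: int,
    seed: int = 0,
) -> List[InteractionPair]:
    """Draw n pairs whose localization term sets are disjoint, label 0.

    Only proteins with at least one localization term are eligible (an
    unannotated protein carries no evidence of spatial separation).  Raises
    with the achievable count if fewer than n disjoint pairs exist.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    annotated = sorted(
        (r for r in proteins if r.localization), key=lambda r: r.id
    )
    pos = _positive_keys(positives)
    eligible = [
        pair_key(a.id, b.id)
        for a, b in itertools.combinations(annotated, 2)
        if not (a.localization & b.localization)
        and pair_key(a.id, b.id) not in pos
    ]
    if n > len(eligible):
        raise ValueError(
            f"requested {n} location negatives but only {len(eligible)} "
            f"localization-disjoint pairs are available"
        )
    if n == 0:
        return []
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [
        InteractionPair(*eligible[i], 0, "location_neg") for i in sorted(idx)
    ]


def sample_edited_negatives(
    positives: Sequence[InteractionPair],
    records: Mapping[str, ProteinRecord] | Sequence[ProteinRecord],
    n: int,
    edit_fraction_range: Tuple[float, float] = (0.20, 0.80),
    seed: int = 0,
    alphabet: AminoAcidAlphabet = DEFAULT_ALPHABET,
) -> Tuple[List[InteractionPair], List[ProteinRecord]]:
    """Mutate one partner of n sampled positives into a synthetic variant.

    For each sampled positive, a fraction f drawn uniformly from
    ``edit_fraction_range`` of one member's positions is substituted with
    random *different* residues, so the Hamming difference equals
    ``round(f * len)`` exactly.  The variant pair is labeled 0 with
    provenance ``edited_neg``; the synthesized variant records are returned
    alongside so they can be written to FASTA and encoded.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    positives = list(positives)
    if n > 0 and not positives:
        raise ValueError("cannot derive edited negatives from an empty positive set")
    if n > len(positives):
        raise ValueError(
            f"requested {n} edited negatives but only {len(positives)} positives exist"
        )
    lo, hi = edit_fraction_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError("edit_fraction_range must satisfy 0 < lo <= hi < 1")
    by_id = (
        dict(records) if isinstance(records, Mapping) else {r.id: r for r in records}
    )
    rng = np.random.default_rng(seed)
    order = rng.choice(len(positives), size=n, replace=False)
    residues = alphabet.ordered_residues
    pairs: List[InteractionPair] = []
    variants: List[ProteinRecord] = []
    for count, idx in enumerate(order):
        pos = positives[idx]
        edit_b = bool(rng.integers(0, 2))
        target_id, partner_id = (
            (pos.id_b, pos.id_a) if edit_b else (pos.id_a, pos.id_b)
        )
        seq = list(by_id[target_id].sequence)
        f = rng.uniform(lo, hi)
        n_edit = int(round(f * len(seq)))
        sites = rng.choice(len(seq), size=n_edit, replace=False)
        for s in sites:
            choices = [r for r in residues if r != seq[s]]
            seq[s] = choices[rng.integers(0, len(choices))]
        variant = ProteinRecord(
            id=f"{target_id}__edit{count}", sequence="".join(seq)
        )
        variants.append(variant)
        pairs.append(
            InteractionPair(partner_id, variant.id, 0, "edited_neg")
            if edit_b
            else InteractionPair(variant.id, partner_id, 0, "edited_neg")
        )
    return pairs, variants


def assemble_negatives(
    positives: Sequence[InteractionPair],
    proteins: Sequence[ProteinRecord],
    total: int,
    mix: Mapping[str, float] = None,
    seed: int = 0,
) -> Tuple[List[InteractionPair], List[ProteinRecord]]:
    """Build a negative set of the requested size from the three strategies.

    ``mix`` gives per-strategy fractions (defaults follow the published
    70k location : 70k edited : remainder random proportions).  Strategies
    that cannot supply their share (e.g. no localization annotations) fall
    back to random negatives.  Global pair uniqueness is enforced across
    strategies.
    """
    if mix is None:
        mix = DEFAULT_NEGATIVE_MIX
    rng = np.random.default_rng(seed)
    n_loc = int(round(total * mix.get("location_neg", 0.0)))
    n_edit = int(round(total * mix.get("edited_neg", 0.0)))
    n_edit = min(n_edit, len(positives))
    negatives: List[InteractionPair] = []
    variants: List[ProteinRecord] = []
    try:
        negatives += sample_location_negatives(
            proteins, positives, n_loc, seed=int(rng.integers(2**31))
        )
    except ValueError:
        pass  # covered by the random remainder below
    edited, variants = sample_edited_negatives(
        positives, proteins, n_edit, seed=int(rng.integers(2**31))
    )
    negatives += edited
    n_random = total - len(negatives)
    # already-taken pairs count as "recorded" so strategies never collide
    exclude = list(positives) + [p for p in negatives if p.provenance != "edited_neg"]
    pool = sample_random_negatives(
        exclude, proteins, min_available_random(exclude, proteins, n_random),
        seed=int(rng.integers(2**31)),
    )
    negatives += pool[:n_random]
    if len(negatives) != total:
        raise ValueError(
            f"could not assemble {total} unique negatives (got {len(negatives)})"
        )
    return negatives, variants


def min_available_random(
    exclude: Sequence[InteractionPair], proteins: Sequence[ProteinRecord], n: int
) -> int:
    """Clamp a random-negative request to what the universe can supply."""
    n_prot = len(proteins)
    available = n_prot * (n_prot - 1) // 2 - len({p.key for p in exclude})
    if n > available:
        raise ValueError(
            f"requested {n} random negatives but only {available} are available"
        )
    return n


def degree_threshold_filter(
    pairs: Sequence[InteractionPair], threshold: int
) -> List[InteractionPair]:
    """Keep pairs in which BOTH proteins have >= threshold interactions.

    Degree is the number of distinct unordered pairs each protein appears in
    within the supplied (positive) set.
    """
    degree: Dict[str, int] = {}
    for k in {p.key for p in pairs}:
        for pid in k:
            degree[pid] = degree.get(pid, 0) + 1
    return [
        p
        for p in pairs
        if degree.get(p.id_a, 0) >= threshold and degree.get(p.id_b, 0) >= threshold
    ]


def make_splits(
    pairs: Sequence[InteractionPair],
    test_fraction: float = 0.20,
    k: int = 5,
    seed: int = 0,
) -> DatasetSplit:
    """Stratified 80/20 train/test split plus stratified k folds of the train set.

    Class balance is preserved per split; identical seeds reproduce
    identical splits.  Raises if either class has fewer than k members in
    the training portion.
    """
    pairs = list(pairs)
    labels = np.array([p.label for p in pairs])
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present to build stratified splits")
    idx = np.arange(len(pairs))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=labels
    )
    train = [pairs[i] for i in train_idx]
    test = [pairs[i] for i in test_idx]
    train_labels = labels[train_idx]
    counts = np.bincount(train_labels, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"each class needs >= {k} training members for {k}-fold CV "
            f"(got {counts.tolist()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [
        [train[i] for i in fold_idx]
        for _, fold_idx in skf.split(np.zeros(len(train)), train_labels)
    ]
    return DatasetSplit(train=train, test=test, folds=folds, seed=seed)
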