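"""Sequence-Statistics-Content (SSC) encoding of protein pairs.

A protein pair is mapped to an image-like tensor with up to three channels,
each derived from the raw amino-acid sequences alone:

* **S1 — sequence channel.** Residue identity, coded irregularly as
  ``((i * 12) + 20) / 255`` for alphabet index ``i`` (A=0 ... Y=19), so the
  twenty codes are pairwise distinct, lie in (0, 1], and never collide with
  the bigram codes of the context channel.
* **S2 — statistics channel.** The within-sequence frequency of the residue
  occupying each position, ``num(i) / len``.
* **C — context channel.** The ordered-bigram code of each residue and its
  right neighbour, ``(i * 20 + j) / 400``, giving 400 distinct values and
  making the representation direction-sensitive.

The two sequences of a pair are laid out in opposite directions on a single
flattened axis of ``2 * max_len`` slots (protein A forward and left-aligned,
protein B reversed and right-aligned) with zero padding in between, then each
channel is reshaped row-major to a ``grid_side x grid_side`` plane.  With the
default maximum length of 1800 residues per protein this yields 60 x 60
planes.  Under a pair swap the S1 and S2 planes are exactly centrosymmetric
(reversing the flattened vector of (a, b) gives that of (b, a)) while the
context channel deliberately is not, because bigrams are ordered.

A plain one-hot ``L x 20`` encoding is also provided as a baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "STANDARD_RESIDUES",
    "AminoAcidAlphabet",
    "DEFAULT_ALPHABET",
    "EncodingConfig",
    "SSCTensor",
    "OneHotMatrix",
    "NonstandardResidueError",
    "SequenceLengthError",
    "encode_residue",
    "decode_residue",
    "residue_frequencies",
    "encode_bigram",
    "encode_sequence_channels",
    "encode_interaction",
    "one_hot_encode",
]

logger = logging.getLogger(__name__)

#: The 20 standard residues in alphabetical one-letter order (A=0 ... Y=19).
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

CHANNEL_ORDER = ("S1", "S2", "C")


class NonstandardResidueError(ValueError):
    """A residue outside the 20-letter alphabet was met under the ``reject`` policy."""


class SequenceLengthError(ValueError):
    """A sequence violates the length filter (20..max_len residues)."""


class AminoAcidAlphabet:
    """Ordered 20-letter amino-acid alphabet mapping residues to indices.

    The default ordering is alphabetical by one-letter code, which pins
    M -> 10 and E -> 3 and hence the worked bigram codes
    ``M-E = (10*20+3)/400 = 0.5075`` and ``E-M = 0.1750``.
    """

    def __init__(self, ordered_residues: str = STANDARD_RESIDUES) -> None:
        residues = tuple(ordered_residues)
        if len(residues) != 20 or len(set(residues)) != 20:
            raise ValueError("alphabet must contain exactly 20 distinct residues")
        self._residues = residues
        self._index = {r: i for i, r in enumerate(residues)}

    @property
    def ordered_residues(self) -> Tuple[str, ...]:
        return self._residues

    def index_of(self, residue: str) -> int:
        try:
            return self._index[residue]
        except KeyError:
            raise NonstandardResidueError(
                f"residue {residue!r} is not in the 20-letter alphabet"
            ) from None

    def __contains__(self, residue: str) -> bool:
        return residue in self._index

    def __iter__(self) -> Iterator[str]:
        return iter(self._residues)

    def __len__(self) -> int:
        return 20


DEFAULT_ALPHABET = AminoAcidAlphabet()


@dataclass(frozen=True)
class EncodingConfig:
    """Geometry and policy of the SSC encoder.

    ``2 * max_len`` must equal ``grid_side ** 2`` so that a pair of
    maximum-length sequences exactly fills the grid (default 3600 = 60^2).
    ``channels`` is an ordered subset of (S1, S2, C); S1 is always required.
    ``nonstandard_policy`` decides what happens on residues outside the
    alphabet: ``"reject"`` raises, ``"map_to_zero"`` encodes them as padding.
    """

    max_len: int = 1800
    min_len: int = 20
    grid_side: int = 60
    channels: Tuple[str, ...] = CHANNEL_ORDER
    nonstandard_policy: str = "reject"
    alphabet: AminoAcidAlphabet = field(default=DEFAULT_ALPHABET, repr=False)

    def __post_init__(self) -> None:
        if 2 * self.max_len != self.grid_side**2:
            raise ValueError(
                f"2 * max_len must equal grid_side**2 "
                f"(got 2*{self.max_len} != {self.grid_side}**2)"
            )
        chans = tuple(self.channels)
        if not chans or "S1" not in chans:
            raise ValueError("channels must be nonempty and include S1")
        if any(c not in CHANNEL_ORDER for c in chans):
            raise ValueError(f"unknown channel in {chans}; valid: {CHANNEL_ORDER}")
        # normalise to canonical (S1, S2, C) order
        object.__setattr__(
            self, "channels", tuple(c for c in CHANNEL_ORDER if c in chans)
        )
        if self.nonstandard_policy not in ("reject", "map_to_zero"):
            raise ValueError("nonstandard_policy must be 'reject' or 'map_to_zero'")

    @property
    def per_protein_slots(self) -> int:
        return self.max_len

    @property
    def n_channels(self) -> int:
        return len(self.channels)


DEFAULT_CONFIG = EncodingConfig()


@dataclass(frozen=True)
class SSCTensor:
    """The encoded representation of one protein pair.

    ``values`` has shape ``(grid_side, grid_side, n_channels)`` with every
    cell in [0, 1]; ``channel_order`` names the planes.
    """

    values: np.ndarray
    channel_order: Tuple[str, ...]
    pair_ids: Tuple[str, str]

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def channel(self, name: str) -> np.ndarray:
        """Return one named channel plane."""
        return self.values[:, :, self.channel_order.index(name)]

    def flattened(self, name: str) -> np.ndarray:
        """Return one channel as the flattened (row-major) slot vector."""
        return self.channel(name).reshape(-1)


@dataclass(frozen=True)
class OneHotMatrix:
    """Baseline ``L x 20`` one-hot encoding; one 1 per encoded row."""

    values: np.ndarray
    sequence_length: int


def encode_residue(
    residue: str,
    alphabet: AminoAcidAlphabet = DEFAULT_ALPHABET,
    nonstandard_policy: str = "reject",
) -> float:
    """Sequence-channel code of one residue: ``((i * 12) + 20) / 255``.

    Strictly increasing in the alphabet index i, so the 20 codes are
    distinct; A -> 0.0784, C -> 0.1255, ..., Y -> 0.9725 (4 d.p.).
    """
    if residue not in alphabet:
        if nonstandard_policy == "map_to_zero":
            logger.warning("nonstandard residue %r mapped to 0", residue)
            return 0.0
        raise NonstandardResidueError(
            f"residue {residue!r} is not in the 20-letter alphabet"
        )
    i = alphabet.index_of(residue)
    return ((i * 12) + 20) / 255


def decode_residue(
    code: float, alphabet: AminoAcidAlphabet = DEFAULT_ALPHABET
) -> str:
    """Invert :func:`encode_residue`; raises on padding (0) or unknown codes."""
    i = round((code * 255 - 20) / 12)
    if 0 <= i < 20 and abs(encode_residue(alphabet.ordered_residues[i], alphabet) - code) < 1e-9:
        return alphabet.ordered_residues[i]
    raise ValueError(f"{code!r} is not a residue code")


def residue_frequencies(
    sequence: str,
    alphabet: AminoAcidAlphabet = DEFAULT_ALPHABET,
    nonstandard_policy: str = "reject",
) -> Dict[str, float]:
    """Per-residue fraction ``num(i) / len`` over the whole sequence.

    Fractions sum to 1 whenever every residue is standard.
    """
    if not sequence:
        raise SequenceLengthError("cannot compute residue frequencies of an empty sequence")
    n = len(sequence)
    freqs: Dict[str, float] = {}
    for r in sequence:
        if r not in alphabet:
            if nonstandard_policy == "map_to_zero":
                logger.warning("nonstandard residue %r ignored in frequencies", r)
                continue
            raise NonstandardResidueError(
                f"residue {r!r} is not in the 20-letter alphabet"
            )
        freqs[r] = freqs.get(r, 0.0) + 1.0
    return {r: c / n for r, c in freqs.items()}


def encode_bigram(
    first: str,
    second: str,
    alphabet: AminoAcidAlphabet = DEFAULT_ALPHABET,
    nonstandard_policy: str = "reject",
) -> float:
    """Context-channel code of an ordered residue pair: ``(i * 20 + j) / 400``.

    Ordered, hence asymmetric: M-E -> 0.5075 but E-M -> 0.1750.  The 400
    ordered pairs map to 400 distinct values in [0, 399/400].
    """
    if first not in alphabet or second not in alphabet:
        if nonstandard_policy == "map_to_zero":
            logger.warning("nonstandard bigram (%r, %r) mapped to 0", first, second)
            return 0.0
        bad = first if first not in alphabet else second
        raise NonstandardResidueError(
            f"residue {bad!r} is not in the 20-letter alphabet"
        )
    i = alphabet.index_of(first)
    j = alphabet.index_of(second)
    return (i * 20 + j) / 400


def _channel_vectors(sequence: str, config: EncodingConfig) -> np.ndarray:
    """S1/S2/C vectors (3, len(sequence)) for one sequence as laid out."""
    alphabet = config.alphabet
    policy = config.nonstandard_policy
    n = len(sequence)
    out = np.zeros((3, n), dtype=np.float64)
    freqs = residue_frequencies(sequence, alphabet, policy)
    for k, r in enumerate(sequence):
        out[0, k] = encode_residue(r, alphabet, policy)
        out[1, k] = freqs.get(r, 0.0)
    for k in range(n - 1):
        out[2, k] = encode_bigram(sequence[k], sequence[k + 1], alphabet, policy)
    # the last occupied slot of the context channel stays 0: a residue has
    # no right neighbour there
    return out


def encode_sequence_channels(
    sequence: str, config: EncodingConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Encode one sequence into its three padded channel vectors.

    Returns an array of shape ``(3, per_protein_slots)`` ordered (S1, S2, C):
    ``S1[k]`` is the residue code at position k, ``S2[k]`` the within-sequence
    frequency of that residue, ``C[k]`` the bigram code of positions
    (k, k+1).  Slots at and beyond ``len(sequence)`` are zero padding.
    """
    n = len(sequence)
    if not (config.min_len <= n <= config.max_len):
        raise SequenceLengthError(
            f"sequence length {n} outside the length filter "
            f"[{config.min_len}, {config.max_len}]"
        )
    out = np.zeros((3, config.per_protein_slots), dtype=np.float64)
    out[:, :n] = _channel_vectors(sequence, config)
    return out


def encode_interaction(
    seq_a: str,
    seq_b: str,
    config: EncodingConfig = DEFAULT_CONFIG,
    pair_ids: Tuple[str, str] = ("a", "b"),
) -> SSCTensor:
    """Encode a protein pair into its SSC tensor.

    Per channel, the flattened layout over ``2 * per_protein_slots`` slots is:
    sequence A forward and left-aligned at slots ``[0, len_a)``; sequence B
    *reversed* and right-aligned, ending at the last slot; zeros in between.
    The context channel is computed on each sequence as laid out, i.e. on the
    reversed string for protein B, so bigram direction flips with the layout.
    Each channel vector is reshaped row-major to ``grid_side x grid_side``
    and only the configured channels are emitted, in (S1, S2, C) order.
    """
    total = 2 * config.per_protein_slots
    flat = np.zeros((3, total), dtype=np.float64)
    for name, seq, reverse in (("a", seq_a, False), ("b", seq_b, True)):
        n = len(seq)
        if not (config.min_len <= n <= config.max_len):
            raise SequenceLengthError(
                f"protein {pair_ids[0] if name == 'a' else pair_ids[1]!r}: "
                f"sequence length {n} outside the length filter "
                f"[{config.min_len}, {config.max_len}]"
            )
        laid = seq[::-1] if reverse else seq
        try:
            vecs = _channel_vectors(laid, config)
        except NonstandardResidueError as exc:
            raise NonstandardResidueError(
                f"protein {pair_ids[0] if name == 'a' else pair_ids[1]!r}: {exc}"
            ) from exc
        if reverse:
            flat[:, total - n :] = vecs
        else:
            flat[:, :n] = vecs
    idx = [CHANNEL_ORDER.index(c) for c in config.channels]
    planes = flat[idx].reshape(len(idx), config.grid_side, config.grid_side)
    values = np.moveaxis(planes, 0, -1)
    return SSCTensor(values=values, channel_order=config.channels, pair_ids=pair_ids)


def one_hot_encode(
    sequence: str,
    alphabet: AminoAcidAlphabet = DEFAULT_ALPHABET,
    nonstandard_policy: str = "reject",
) -> OneHotMatrix:
    """Baseline one-hot encoding: ``L x 20`` with a single 1 per encoded row.

    Under ``map_to_zero`` a nonstandard residue yields an all-zero row.
    """
    n = len(sequence)
    values = np.zeros((n, 20), dtype=np.int8)
    for k, r in enumerate(sequence):
        if r not in alphabet:
            if nonstandard_policy == "map_to_zero":
                logger.warning("nonstandard residue %r one-hot encoded as zeros", r)
                continue
            raise NonstandardResidueError(
                f"residue {r!r} is not in the 20-letter alphabet"
            )
        values[k, alphabet.index_of(r)] = 1
    return OneHotMatrix(values=values, sequence_length=n)
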