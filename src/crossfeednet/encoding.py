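"""Binary reaction-profile encoding of organisms and interacting pairs.

Every organism is reduced to a fixed-length 0/1 vector over an ordered
*reaction pool* (the universe of reaction identifiers observed in at least one
organism of the training collection).  A pair of organisms is represented by
the concatenation of the two profiles, so a pair vector has length ``2 * P``
where ``P`` is the pool size.  Because concatenation is order-sensitive, each
labelled pair enters a dataset twice (AB and BA); the two orientations share a
canonical ``pair_key`` so that fold construction can keep them together.
"""

from __future__ import annotations

import hashlib
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from ._exceptions import ValidationError

logger = logging.getLogger(__name__)

#: The two interaction classes.  ``CROSS_FEEDING`` is the majority class in
#: typical literature-derived datasets and is the class whose probability a
#: classifier score reports.
CROSS_FEEDING = "cross_feeding"
COMPETITION = "competition"
LABELS = (CROSS_FEEDING, COMPETITION)


@dataclass(frozen=True)
class ReactionSet:
    """The reactions of one organism's metabolic network (set semantics)."""

    organism_id: str
    reactions: frozenset[str]

    def __post_init__(self):
        if not self.organism_id:
            raise ValidationError("organism_id must be a non-empty string")
        if any(not r for r in self.reactions):
            raise ValidationError(f"{self.organism_id}: empty reaction identifier")

    def __len__(self) -> int:
        return len(self.reactions)


@dataclass(frozen=True)
class InteractionRecord:
    """One labelled unordered pair of organisms."""

    organism_a: str
    organism_b: str
    label: str

    def __post_init__(self):
        if self.organism_a == self.organism_b:
            raise ValidationError(f"self-pair not allowed: {self.organism_a}")
        if self.label not in LABELS:
            raise ValidationError(f"unknown label {self.label!r}; expected one of {LABELS}")

    @property
    def pair_key(self) -> tuple[str, str]:
        return pair_key(self.organism_a, self.organism_b)


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered identifier of a pair: the sorted id tuple."""
    return (a, b) if a <= b else (b, a)


class ReactionPool:
    """Ordered universe of reaction IDs defining the vector coordinates.

    The order is part of the data: coordinates are meaningless without it, so
    the pool is serialized alongside every encoded artifact together with a
    content hash used to detect accidental mixing of pools.
    """

    def __init__(self, reactions: Sequence[str]):
        reactions = list(reactions)
        if not reactions:
            raise ValidationError("reaction pool must be non-empty")
        if len(set(reactions)) != len(reactions):
            dupes = [r for r, n in Counter(reactions).items() if n > 1]
            raise ValidationError(f"duplicate reaction IDs in pool: {dupes[:5]}")
        self.reactions: tuple[str, ...] = tuple(reactions)
        self._index = {r: i for i, r in enumerate(self.reactions)}

    def __len__(self) -> int:
        return len(self.reactions)

    def __iter__(self):
        return iter(self.reactions)

    def __contains__(self, reaction: str) -> bool:
        return reaction in self._index

    def __eq__(self, other) -> bool:
        return isinstance(other, ReactionPool) and self.reactions == other.reactions

    def index(self, reaction: str) -> int:
        return self._index[reaction]

    @property
    def content_hash(self) -> str:
        """SHA-256 of the newline-joined, ordered reaction IDs."""
        return hashlib.sha256("\n".join(self.reactions).encode()).hexdigest()

    def __repr__(self) -> str:
        return f"ReactionPool(P={len(self)}, hash={self.content_hash[:8]})"


@dataclass
class OrganismProfile:
    """Binary presence vector of one organism over a reaction pool."""

    organism_id: str
    bits: np.ndarray
    pool_hash: str

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 1:
            raise ValidationError("profile bits must be one-dimensional")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValidationError("profile bits must be 0/1")
        if int(self.bits.sum()) == 0:
            raise ValidationError(
                f"{self.organism_id}: no pooled reactions (all-zero profile rejected)"
            )

    def __len__(self) -> int:
        return len(self.bits)


@dataclass
class PairVector:
    """Oriented pair representation: profile of *first* then of *second*."""

    first_id: str
    second_id: str
    bits: np.ndarray
    label: Optional[str] = None

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.label is not None and self.label not in LABELS:
            raise ValidationError(f"unknown label {self.label!r}")

    @property
    def pair_key(self) -> tuple[str, str]:
        return pair_key(self.first_id, self.second_id)

    @property
    def is_canonical(self) -> bool:
        """True when (first, second) is the lexicographically sorted orientation."""
        return (self.first_id, self.second_id) == self.pair_key


@dataclass
class PairDataset:
    """A collection of oriented pair vectors over one pool.

    After augmentation every ``pair_key`` occurs exactly twice with opposite
    orientations and identical labels.
    """

    pool: ReactionPool
    vectors: list[PairVector]
    class_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.class_counts:
            self.class_counts = dict(
                Counter(v.label for v in self.vectors if v.label is not None)
            )
        self._matrix: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.vectors)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_keys_unique())

    def pair_keys(self) -> list[tuple[str, str]]:
        return [v.pair_key for v in self.vectors]

    def pair_keys_unique(self) -> list[tuple[str, str]]:
        seen: dict[tuple[str, str], None] = {}
        for v in self.vectors:
            seen.setdefault(v.pair_key, None)
        return list(seen)

    def labels(self) -> np.ndarray:
        return np.array([v.label for v in self.vectors], dtype=object)

    def matrix(self) -> np.ndarray:
        """All oriented vectors stacked row-wise (uint8, cached)."""
        if self._matrix is None:
            self._matrix = np.vstack([v.bits for v in self.vectors]).astype(np.uint8)
        return self._matrix

    def validate(self) -> None:
        width = 2 * len(self.pool)
        for v in self.vectors:
            if v.bits.shape != (width,):
                raise ValidationError(
                    f"pair {v.first_id}/{v.second_id}: vector length {v.bits.size} != 2P={width}"
                )
        by_key: dict[tuple[str, str], list[PairVector]] = {}
        for v in self.vectors:
            by_key.setdefault(v.pair_key, []).append(v)
        for key, group in by_key.items():
            if len(group) != 2:
                raise ValidationError(f"pair {key}: expected 2 orientations, found {len(group)}")
            labels = {v.label for v in group}
            if len(labels) != 1:
                raise ValidationError(f"pair {key}: orientations disagree on label {labels}")
            orientations = {(v.first_id, v.second_id) for v in group}
            if len(orientations) != 2:
                raise ValidationError(f"pair {key}: duplicated orientation")
        if sum(self.class_counts.values()) != len(self.vectors):
            raise ValidationError("class counts do not sum to the vector count")


def build_reaction_pool(
    reference: Sequence[str], organisms: Iterable[ReactionSet]
) -> ReactionPool:
    """Filter a reference reaction list down to the working pool.

    Keeps, in reference order, every reaction present in at least one
    organism.  Reactions no organism carries would be constant-zero features
    and are dropped.
    """
    reference = list(dict.fromkeys(reference))  # dedupe, keep first occurrence
    if not reference:
        raise ValidationError("reference reaction list is empty")
    organisms = list(organisms)
    if not organisms:
        raise ValidationError("at least one organism is required to build a pool")
    union: set[str] = set()
    for org in organisms:
        union |= org.reactions
    kept = [r for r in reference if r in union]
    if not kept:
        raise ValidationError("no organism shares reactions with the reference")
    dropped = len(reference) - len(kept)
    if dropped:
        logger.info("pool filter: kept %d of %d reference reactions (%d constant-zero dropped)",
                    len(kept), len(reference), dropped)
    return ReactionPool(kept)


def encode_profile(organism: ReactionSet, pool: ReactionPool) -> OrganismProfile:
    """Encode one organism as a 0/1 vector over the pool coordinates.

    Reactions carried by the organism but absent from the pool (exchange and
    sink reactions emitted by reconstruction tools, typically) are ignored
    with a logged count rather than raising.
    """
    bits = np.zeros(len(pool), dtype=np.uint8)
    ignored = 0
    for reaction in organism.reactions:
        if reaction in pool:
            bits[pool.index(reaction)] = 1
        else:
            ignored += 1
    if ignored:
        logger.debug("%s: %d reactions outside the pool ignored", organism.organism_id, ignored)
    if int(bits.sum()) == 0:
        raise ValidationError(
            f"{organism.organism_id}: organism has zero reactions in the pool"
        )
    return OrganismProfile(organism.organism_id, bits, pool.content_hash)


def encode_pair(a: OrganismProfile, b: OrganismProfile, label: Optional[str] = None) -> PairVector:
    """Concatenate two profiles into an oriented pair vector of length 2P."""
    if a.pool_hash != b.pool_hash:
        raise ValidationError(
            f"profiles {a.organism_id} and {b.organism_id} were encoded on different pools"
        )
    if len(a) != len(b):
        raise ValidationError("profile lengths differ")
    return PairVector(a.organism_id, b.organism_id, np.concatenate([a.bits, b.bits]), label)


def augment_dataset(
    records: Sequence[InteractionRecord],
    profiles: Mapping[str, OrganismProfile],
    pool: ReactionPool,
) -> PairDataset:
    """Build the oriented, AB/BA-augmented dataset from labelled records.

    Each record contributes both orientations with the same label, doubling
    the dataset and removing positional bias.  Exact duplicate records are
    deduplicated with a warning; the same unordered pair carrying two
    different labels is a hard error.
    """
    seen: dict[tuple[str, str], str] = {}
    conflicts = []
    unique_records: list[InteractionRecord] = []
    for rec in records:
        key = rec.pair_key
        if key in seen:
            if seen[key] != rec.label:
                conflicts.append((key, seen[key], rec.label))
            else:
                logger.warning("duplicate record for pair %s deduplicated", key)
            continue
        seen[key] = rec.label
        unique_records.append(rec)
    if conflicts:
        raise ValidationError(f"conflicting labels for pairs: {conflicts}")
    if not unique_records:
        raise ValidationError("no interaction records to encode")

    vectors: list[PairVector] = []
    for rec in unique_records:
        for first, second in ((rec.organism_a, rec.organism_b), (rec.organism_b, rec.organism_a)):
            try:
                pa, pb = profiles[first], profiles[second]
            except KeyError as exc:
                raise ValidationError(f"no profile for organism {exc.args[0]!r}") from None
            vectors.append(encode_pair(pa, pb, rec.label))
    dataset = PairDataset(pool=pool, vectors=vectors)
    dataset.validate()
    return dataset
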