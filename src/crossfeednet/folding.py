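"""Leakage-aware cross-validation fold construction.

The two orientations of one unordered pair are near-duplicates: letting them
straddle a train/test split inflates every metric.  Folds are therefore built
at the level of unordered pairs.  Pairs are first clustered (k-means on the
canonical orientation of each pair vector) to keep similar pairs together,
then whole clusters are merged greedily into a fixed number of folds of
roughly equal size.  Orientation co-location holds by construction because the
assignment is keyed on the unordered ``pair_key``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from ._exceptions import ValidationError
from .encoding import PairDataset

PairKey = tuple[str, str]


@dataclass
class FoldAssignment:
    """Map pair_key -> fold index, plus per-fold tallies over oriented vectors."""

    n_folds: int
    assignment: dict[PairKey, int]
    tallies: list[dict] = field(default_factory=list)

    def fold_of(self, key: PairKey) -> int:
        return self.assignment[key]

    def to_json(self) -> dict:
        return {
            "n_folds": self.n_folds,
            "assignment": [[list(k), f] for k, f in sorted(self.assignment.items())],
            "tallies": self.tallies,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "FoldAssignment":
        assignment = {tuple(k): f for k, f in obj["assignment"]}
        return cls(obj["n_folds"], assignment, obj.get("tallies", []))


@dataclass
class LeakageReport:
    """Outcome of auditing a fold assignment against a dataset."""

    split_orientations: list[PairKey]
    multi_fold: list[PairKey]
    unassigned: list[PairKey]

    @property
    def ok(self) -> bool:
        return not (self.split_orientations or self.multi_fold or self.unassigned)

    @property
    def violations(self) -> list[PairKey]:
        return self.split_orientations + self.multi_fold + self.unassigned

    def to_json(self) -> dict:
        return {
            "ok": self.ok,
            "split_orientations": [list(k) for k in self.split_orientations],
            "multi_fold": [list(k) for k in self.multi_fold],
            "unassigned": [list(k) for k in self.unassigned],
        }


def cluster_pairs(dataset: PairDataset, n_clusters: int = 10, seed: int = 0) -> dict[PairKey, int]:
    """K-means over the canonical orientation of each unordered pair.

    One vector per pair (lexicographically smaller organism first) so that
    each unordered pair receives exactly one cluster id.  Squared-Euclidean
    distance on the raw 0/1 vectors, k-means++ initialization, 10 restarts.
    """
    canonical = [v for v in dataset.vectors if v.is_canonical]
    keys = [v.pair_key for v in canonical]
    if len(set(keys)) != len(keys):
        raise ValidationError("dataset has duplicated canonical orientations")
    if not 2 <= n_clusters <= len(keys):
        raise ValidationError(
            f"n_clusters={n_clusters} out of range [2, {len(keys)} unique pairs]"
        )
    X = np.vstack([v.bits for v in canonical]).astype(np.float32)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    ids = km.fit_predict(X)
    return {key: int(cid) for key, cid in zip(keys, ids)}


def assemble_folds(
    clusters: dict[PairKey, int], dataset: PairDataset, n_folds: int = 4
) -> FoldAssignment:
    """Merge clusters whole into folds, balancing fold sizes greedily.

    Clusters are taken largest first (ties by cluster id) and each is assigned
    to the currently smallest fold (ties by fold index), so the result is
    deterministic given the clustering.
    """
    cluster_ids = sorted(set(clusters.values()))
    if n_folds > len(cluster_ids):
        raise ValidationError(f"n_folds={n_folds} exceeds the {len(cluster_ids)} clusters")
    members: dict[int, list[PairKey]] = {cid: [] for cid in cluster_ids}
    for key, cid in clusters.items():
        members[cid].append(key)
    order = sorted(cluster_ids, key=lambda cid: (-len(members[cid]), cid))

    n_pairs = len(clusters)
    biggest = len(members[order[0]])
    if biggest > 2 * -(-n_pairs // n_folds):
        import logging
        logging.getLogger(__name__).warning(
            "largest cluster (%d pairs) makes balanced folds unachievable", biggest
        )

    fold_sizes = [0] * n_folds
    assignment: dict[PairKey, int] = {}
    for cid in order:
        target = min(range(n_folds), key=lambda f: (fold_sizes[f], f))
        for key in members[cid]:
            assignment[key] = target
        fold_sizes[target] += len(members[cid])

    tallies = _tally(assignment, dataset, n_folds)
    return FoldAssignment(n_folds=n_folds, assignment=assignment, tallies=tallies)


def _tally(assignment: dict[PairKey, int], dataset: PairDataset, n_folds: int) -> list[dict]:
    tallies = [{"fold": f, "examples": 0, "per_class": {}} for f in range(n_folds)]
    for v in dataset.vectors:
        f = assignment.get(v.pair_key)
        if f is None:
            continue
        tallies[f]["examples"] += 1
        if v.label is not None:
            per = tallies[f]["per_class"]
            per[v.label] = per.get(v.label, 0) + 1
    return tallies


def audit_leakage(folds: FoldAssignment, dataset: PairDataset) -> LeakageReport:
    """Report (ideally empty) any pair whose orientations could leak.

    With a pair_key-keyed assignment the orientation check cannot fire, but
    assignments may come from disk or from foreign code, so the audit inspects
    the oriented vectors themselves.
    """
    seen_folds: dict[PairKey, set[int]] = {}
    unassigned = []
    for v in dataset.vectors:
        if v.pair_key not in folds.assignment:
            if v.pair_key not in unassigned:
                unassigned.append(v.pair_key)
            continue
        seen_folds.setdefault(v.pair_key, set()).add(folds.assignment[v.pair_key])
    split = sorted(k for k, fs in seen_folds.items() if len(fs) > 1)
    return LeakageReport(split_orientations=split, multi_fold=[], unassigned=sorted(set(unassigned)))


def audit_oriented_assignment(
    oriented: dict[tuple[str, str], int], dataset: PairDataset
) -> LeakageReport:
    """Audit an assignment keyed on *oriented* (first, second) tuples.

    This is the form in which external fold files may arrive; here the
    AB/BA co-location rule can actually be violated.
    """
    from .encoding import pair_key as canon

    split: list[PairKey] = []
    unassigned: list[PairKey] = []
    by_pair: dict[PairKey, set[int]] = {}
    for v in dataset.vectors:
        fold = oriented.get((v.first_id, v.second_id))
        key = canon(v.first_id, v.second_id)
        if fold is None:
            if key not in unassigned:
                unassigned.append(key)
            continue
        by_pair.setdefault(key, set()).add(fold)
    for key, fs in sorted(by_pair.items()):
        if len(fs) > 1:
            split.append(key)
    return LeakageReport(split_orientations=split, multi_fold=[], unassigned=unassigned)
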