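"""Readers and writers for every on-disk representation the pipeline touches.

Formats
-------
* plain-text reaction lists: one reaction ID per line, ``#`` comments and
  blank lines ignored;
* SBML (level 2/3): only reaction identifiers are used — stoichiometry,
  bounds and gene rules are ignored;
* interaction tables: TSV with header ``organism_a  organism_b  label``;
* score matrices: CSV with organism IDs as first row and first column;
* encoded pair datasets: TSV (optionally gzipped) plus a JSON sidecar that
  carries the pool, its content hash and the class counts;
* fold assignments and metric reports: JSON.
"""

from __future__ import annotations

import gzip
import json
import logging
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from ._exceptions import ParseError, ValidationError
from .encoding import (
    COMPETITION,
    CROSS_FEEDING,
    InteractionRecord,
    PairDataset,
    PairVector,
    ReactionPool,
    ReactionSet,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: Accepted label spellings, all mapped onto the two-class enum.
LABEL_ALIASES = {
    "cross-feeding": CROSS_FEEDING,
    "cross_feeding": CROSS_FEEDING,
    "cf": CROSS_FEEDING,
    "competition": COMPETITION,
    "co": COMPETITION,
}


def normalize_label(raw: str) -> str:
    try:
        return LABEL_ALIASES[raw.strip().lower()]
    except KeyError:
        raise ValidationError(f"unknown interaction label {raw!r}") from None


# ---------------------------------------------------------------------------
# reaction lists
# ---------------------------------------------------------------------------

def read_reaction_list(path: PathLike, organism_id: str | None = None) -> ReactionSet:
    """Read a plain-text reaction list; organism_id defaults to the file stem."""
    path = Path(path)
    reactions = set()
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        reactions.add(line)
    if not reactions:
        raise ValidationError(f"{path}: no reaction IDs found")
    return ReactionSet(organism_id or path.stem, frozenset(reactions))


def write_reaction_list(reactions: Sequence[str] | ReactionSet, path: PathLike) -> None:
    path = Path(path)
    if isinstance(reactions, ReactionSet):
        ids = sorted(reactions.reactions)
    else:
        ids = list(reactions)
    path.write_text("\n".join(ids) + "\n")


def read_reference_pool(path: PathLike) -> list[str]:
    """Read an *ordered* reference reaction list (order defines coordinates)."""
    path = Path(path)
    ids: list[str] = []
    seen = set()
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line not in seen:
            seen.add(line)
            ids.append(line)
    if not ids:
        raise ValidationError(f"{path}: empty reference pool")
    return ids


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def read_sbml_reactions(path: PathLike) -> ReactionSet:
    """Extract the reaction identifier set from an SBML file."""
    import libsbml

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromString(path.read_text())
    if doc.getNumErrors() > 0:
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                raise ParseError(f"{path}: SBML parse error: {err.getMessage().strip()}")
    model = doc.getModel()
    if model is None:
        raise ParseError(f"{path}: no SBML model element")
    ids: list[str] = [model.getReaction(i).getId() for i in range(model.getNumReactions())]
    dupes = {r for r in ids if ids.count(r) > 1}
    if dupes:
        raise ValidationError(f"{path}: duplicate reaction ids {sorted(dupes)}")
    if not ids:
        raise ValidationError(f"{path}: SBML model contains zero reactions")
    organism_id = model.getId() or path.stem
    return ReactionSet(organism_id, frozenset(ids))


def write_sbml(reactions: ReactionSet, path: PathLike) -> None:
    """Write a minimal reaction-only SBML (level 3 version 1) stub."""
    import libsbml

    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel()
    model.setId(reactions.organism_id)
    for rid in sorted(reactions.reactions):
        rxn = model.createReaction()
        rxn.setId(rid)
        rxn.setReversible(False)
        rxn.setFast(False)
    Path(path).write_text(libsbml.writeSBMLToString(doc))


# ---------------------------------------------------------------------------
# interaction tables
# ---------------------------------------------------------------------------

def read_interaction_table(path: PathLike) -> list[InteractionRecord]:
    """Read a TSV of labelled pairs; labels are normalized case-insensitively."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"organism_a", "organism_b", "label"}
    if not required.issubset(frame.columns):
        raise ValidationError(f"{path}: missing columns {sorted(required - set(frame.columns))}")
    records = []
    for idx, row in frame.iterrows():
        line_no = int(idx) + 2  # header is line 1
        try:
            label = normalize_label(row["label"])
            records.append(InteractionRecord(row["organism_a"], row["organism_b"], label))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{line_no}: {exc}") from None
    return records


def write_interaction_table(records: Sequence[InteractionRecord], path: PathLike) -> None:
    frame = pd.DataFrame(
        [(r.organism_a, r.organism_b, r.label) for r in records],
        columns=["organism_a", "organism_b", "label"],
    )
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# score matrices
# ---------------------------------------------------------------------------

def read_score_matrix(path: PathLike) -> pd.DataFrame:
    """Read a labelled square matrix of real-valued pairwise scores (CSV)."""
    path = Path(path)
    frame = pd.read_csv(path, index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if frame.shape[0] != frame.shape[1]:
        raise ValidationError(f"{path}: matrix is {frame.shape[0]}x{frame.shape[1]}, not square")
    if list(frame.index) != list(frame.columns):
        raise ValidationError(f"{path}: row and column labels differ")
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad):
            raise ParseError(f"{path}: non-numeric cell at ({bad[0]}, {col})")
        frame[col] = coerced
    return frame


def write_score_matrix(matrix: pd.DataFrame, path: PathLike) -> None:
    matrix.to_csv(path)


# ---------------------------------------------------------------------------
# encoded pair datasets
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".tsv.gz", ".tsv"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".meta.json")
    return path.with_name(name + ".meta.json")


def write_pair_dataset(dataset: PairDataset, path: PathLike) -> Path:
    """Persist an encoded dataset as (gzipped) TSV plus a JSON sidecar.

    The sidecar stores the ordered pool and its content hash so that the
    dataset can be reloaded without the original network files, and so that
    artifacts from different pools are never silently mixed.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write("pair_key\tfirst_id\tsecond_id\tlabel\tbits\n")
        for v in dataset.vectors:
            key = "|".join(v.pair_key)
            bitstring = np.packbits(v.bits).tobytes().hex()
            fh.write(f"{key}\t{v.first_id}\t{v.second_id}\t{v.label or ''}\t{bitstring}\n")
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({
        "pool": list(dataset.pool.reactions),
        "pool_hash": dataset.pool.content_hash,
        "P": len(dataset.pool),
        "N": len(dataset),
        "class_counts": dataset.class_counts,
    }))
    return sidecar


def read_pair_dataset(path: PathLike) -> PairDataset:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValidationError(f"{path}: sidecar {sidecar.name} not found")
    meta = json.loads(sidecar.read_text())
    pool = ReactionPool(meta["pool"])
    if pool.content_hash != meta["pool_hash"]:
        raise ValidationError(f"{sidecar}: pool content hash mismatch")
    width = 2 * len(pool)
    vectors = []
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        header = fh.readline()
        if not header.startswith("pair_key"):
            raise ParseError(f"{path}: unexpected header {header!r}")
        for line in fh:
            _, first, second, label, bitstring = line.rstrip("\n").split("\t")
            bits = np.unpackbits(np.frombuffer(bytes.fromhex(bitstring), dtype=np.uint8))[:width]
            vectors.append(PairVector(first, second, bits, label or None))
    dataset = PairDataset(pool=pool, vectors=vectors)
    if len(dataset) != meta["N"]:
        raise ValidationError(f"{path}: expected {meta['N']} vectors, read {len(dataset)}")
    return dataset


# ---------------------------------------------------------------------------
# JSON artifacts
# ---------------------------------------------------------------------------

def write_json(obj, path: PathLike) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def read_json(path: PathLike):
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
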