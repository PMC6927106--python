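"""Readers and writers: annotation tables, protein-network edge lists,
matrix serialization and model bundles.

Annotation tables are TSV files with one (protein, term) pair per row;
protein networks are STRING-style edge lists with a confidence score per
pair.  All matrices leaving this module are index-aligned: the annotation
table defines the protein universe and networks are re-indexed onto it.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import AnnotationMatrix, EntityIndex, MaskMatrix, SimilarityNetwork
from .ontology import AnnotationSet

__all__ = [
    "read_annotation_table",
    "write_annotation_table",
    "build_matrix",
    "read_ppn",
    "write_ppn",
    "write_obo",
    "align_to_index",
    "make_mask",
    "save_model",
    "load_model",
    "write_network",
    "read_network",
    "write_predictions",
]

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


def read_annotation_table(
    source: str | Path | IO[str],
    protein_col: int = 0,
    term_col: int = 1,
    sep: str = "\t",
) -> AnnotationSet:
    """Read a (protein, term) annotation TSV into a de-duplicated pair set.

    Lines starting with '#' are skipped; malformed rows (too few columns or
    empty fields) are skipped with a logged warning.  Zero usable rows is a
    hard error.
    """
    needed = max(protein_col, term_col) + 1
    df = pd.read_csv(
        source, sep=sep, comment="#", header=None, dtype=str, engine="python"
    )
    if df.shape[1] < needed:
        raise ValueError(
            f"annotation table has {df.shape[1]} columns, need {needed}"
        )
    pairs: set[tuple[str, str]] = set()
    n_bad = 0
    for row in df.itertuples(index=False):
        protein, term = row[protein_col], row[term_col]
        if pd.isna(protein) or pd.isna(term) or not str(protein) or not str(term):
            n_bad += 1
            continue
        pairs.add((str(protein).strip(), str(term).strip()))
    if n_bad:
        logger.warning("skipped %d malformed annotation rows", n_bad)
    if not pairs:
        raise ValueError("annotation table contains no usable rows")
    return AnnotationSet(pairs=frozenset(pairs))


def build_matrix(
    ann: AnnotationSet,
    proteins: EntityIndex | None = None,
    terms: EntityIndex | None = None,
) -> AnnotationMatrix:
    """Binary matrix Y with Y[i, j] = 1 iff (protein i, term j) is annotated.

    Indexes default to the proteins/terms present in the annotation set;
    pairs whose ids are missing from an explicit index are dropped with a
    warning.
    """
    if not ann.pairs:
        raise ValueError("empty annotation set")
    proteins = proteins or EntityIndex.from_ids(ann.proteins)
    terms = terms or EntityIndex.from_ids(ann.terms)
    values = np.zeros((len(proteins), len(terms)))
    n_dropped = 0
    for protein, term in ann.pairs:
        if protein in proteins and term in terms:
            values[proteins.position(protein), terms.position(term)] = 1.0
        else:
            n_dropped += 1
    if n_dropped:
        logger.warning("dropped %d pairs outside the given indexes", n_dropped)
    return AnnotationMatrix(values=values, row_index=proteins, col_index=terms)


def read_ppn(
    source: str | Path | IO[str],
    scale: float = 1.0,
    score_col: int | str = 2,
    protein_cols: tuple[int, int] = (0, 1),
    sep: str | None = None,
    header: bool | None = None,
) -> SimilarityNetwork:
    """Read a weighted protein-protein edge list into a SimilarityNetwork.

    Scores are divided by ``scale`` (e.g. 1000 for STRING's 0-1000 combined
    score) so weights land in [0, 1].  Duplicate/reciprocal edges are merged
    by taking the maximum; self-edges are dropped.  A negative score is a
    hard error.  ``sep=None`` splits on any whitespace (the STRING links
    dialect); ``header`` defaults to auto-detection, and a named
    ``score_col`` implies a header line.
    """
    if header is None and not isinstance(score_col, str):
        # sniff: a non-numeric score field on the first line means a header
        df0 = pd.read_csv(
            source,
            sep=sep if sep is not None else r"\s+",
            comment="#",
            header=None,
            engine="python",
            dtype=str,
        )
        try:
            float(df0.iloc[0, score_col if isinstance(score_col, int) else 2])
            header = False
        except (TypeError, ValueError):
            header = True
        if header:
            df0.columns = df0.iloc[0]
            df = df0.iloc[1:].reset_index(drop=True)
        else:
            df = df0
    else:
        if header is None:
            header = True
        df = pd.read_csv(
            source,
            sep=sep if sep is not None else r"\s+",
            comment="#",
            header=0 if header else None,
            engine="python",
        )
    a_col, b_col = protein_cols
    a = df.iloc[:, a_col].astype(str)
    b = df.iloc[:, b_col].astype(str)
    if isinstance(score_col, str):
        if score_col not in df.columns:
            raise ValueError(f"no column named {score_col!r} in edge list")
        score = df[score_col].astype(float)
    else:
        score = df.iloc[:, score_col].astype(float)
    if (score < 0).any():
        raise ValueError("negative edge score in protein network")

    weights_map: dict[tuple[str, str], float] = {}
    for pa, pb, s in zip(a, b, score / scale):
        if pa == pb:
            continue
        key = (pa, pb) if pa < pb else (pb, pa)
        prev = weights_map.get(key)
        if prev is None or s > prev:
            weights_map[key] = float(s)

    ids = {p for pair in weights_map for p in pair}
    index = EntityIndex.from_ids(ids) if ids else EntityIndex(ids=())
    n = len(index)
    mat = np.zeros((n, n))
    for (pa, pb), w in weights_map.items():
        i, j = index.position(pa), index.position(pb)
        mat[i, j] = mat[j, i] = w
    return SimilarityNetwork(weights=mat, index=index, kind="protein")


def align_to_index(
    net: SimilarityNetwork, target: EntityIndex
) -> SimilarityNetwork:
    """Re-index a network onto ``target``.

    Entities absent from the network get all-zero rows/columns; entities
    absent from ``target`` are dropped.
    """
    n = len(target)
    out = np.zeros((n, n))
    shared = [e for e in net.index.ids if e in target]
    src = np.array([net.index.position(e) for e in shared], dtype=int)
    dst = np.array([target.position(e) for e in shared], dtype=int)
    if len(shared):
        out[np.ix_(dst, dst)] = net.weights[np.ix_(src, src)]
    return SimilarityNetwork(weights=out, index=target, kind=net.kind)


def make_mask(
    shape: tuple[int, int], heldout: Iterable[tuple[int, int]] = ()
) -> MaskMatrix:
    """All-ones mask W with zeros exactly at the held-out (i, j) cells."""
    values = np.ones(shape)
    for i, j in heldout:
        if not (0 <= i < shape[0] and 0 <= j < shape[1]):
            raise IndexError(f"held-out cell {(i, j)} outside shape {shape}")
        values[i, j] = 0.0
    return MaskMatrix(values=values)


def write_annotation_table(
    ann: AnnotationSet | AnnotationMatrix, path: str | Path
) -> None:
    """Write (protein, term) pairs as a sorted two-column TSV."""
    pairs = ann.pairs() if isinstance(ann, AnnotationMatrix) else set(ann.pairs)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("#protein\tterm\n")
        for protein, term in sorted(pairs):
            fh.write(f"{protein}\t{term}\n")


def write_ppn(
    net: SimilarityNetwork, path: str | Path, scale: float = 1.0
) -> None:
    """Write a network as a three-column edge list (scores multiplied back
    by ``scale``), one undirected edge per row."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        rows, cols = np.nonzero(np.triu(net.weights, k=1))
        for i, j in zip(rows.tolist(), cols.tolist()):
            fh.write(
                f"{net.index.ids[i]} {net.index.ids[j]} "
                f"{net.weights[i, j] * scale:.17g}\n"
            )


def write_obo(dag, path: str | Path) -> None:
    """Write an is-a DAG as a minimal OBO 1.2 flat file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["format-version: 1.2", "ontology: synthetic-toy", ""]
    for term in sorted(dag.terms):
        lines += [f"[Term]", f"id: {term}", f"name: {term}"]
        for parent in sorted(dag.parent_map.get(term, ())):
            lines.append(f"is_a: {parent}")
        lines.append("")
    path.write_text("\n".join(lines))


# --- serialization -----------------------------------------------------------


def _mmwrite(path: Path, arr: np.ndarray) -> None:
    spio.mmwrite(str(path), sparse.coo_matrix(arr), precision=17)


def _mmread(path: Path) -> np.ndarray:
    mat = spio.mmread(str(path))
    if sparse.issparse(mat):
        mat = mat.toarray()
    return np.asarray(mat, dtype=np.float64)


def save_model(model, path: str | Path) -> None:
    """Write a factor model as one MTX per factor plus a JSON header."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _mmwrite(path / "U.mtx", model.U)
    _mmwrite(path / "V.mtx", model.V)
    header = {
        "format_version": MODEL_FORMAT_VERSION,
        "hyperparams": {
            "K": model.hyper.K,
            "lam": model.hyper.lam,
            "alpha": model.hyper.alpha,
            "beta": model.hyper.beta,
            "max_iter": model.hyper.max_iter,
            "tol": model.hyper.tol,
            "seed": model.hyper.seed,
        },
        "objective_trace": list(map(float, model.objective_trace)),
    }
    (path / "model.json").write_text(json.dumps(header, indent=2))


def load_model(path: str | Path):
    """Load a model bundle written by :func:`save_model`."""
    from .factorization import FactorModel, Hyperparams

    path = Path(path)
    header_path = path / "model.json"
    if not path.exists() or not header_path.exists():
        raise FileNotFoundError(f"no model bundle at {path}")
    header = json.loads(header_path.read_text())
    if header.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {header.get('format_version')} "
            f"!= supported {MODEL_FORMAT_VERSION}"
        )
    hyper = Hyperparams(**header["hyperparams"])
    U = _mmread(path / "U.mtx")
    V = _mmread(path / "V.mtx")
    return FactorModel(
        U=U, V=V, hyper=hyper, objective_trace=list(header["objective_trace"])
    )


def write_network(net: SimilarityNetwork, prefix: str | Path) -> None:
    """Write a network as symmetric-coordinate MTX plus an index TSV."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(
        str(prefix.with_suffix(".mtx")),
        sparse.coo_matrix(net.weights),
        symmetry="symmetric",
        precision=17,
    )
    lines = [f"{i}\t{name}" for i, name in enumerate(net.index.ids)]
    prefix.with_suffix(".index.tsv").write_text("\n".join(lines) + "\n")


def read_network(prefix: str | Path, kind: str) -> SimilarityNetwork:
    prefix = Path(prefix)
    mat = spio.mmread(str(prefix.with_suffix(".mtx")))
    if sparse.issparse(mat):
        mat = mat.toarray()
    ids = [
        line.split("\t")[1]
        for line in prefix.with_suffix(".index.tsv").read_text().splitlines()
        if line
    ]
    return SimilarityNetwork(
        weights=np.asarray(mat, dtype=np.float64),
        index=EntityIndex.from_ids(ids),
        kind=kind,
    )


def write_predictions(
    scores: np.ndarray,
    proteins: EntityIndex,
    terms: EntityIndex,
    path: str | Path,
    top: int | None = None,
    exclude: np.ndarray | None = None,
) -> int:
    """Write (protein, term, score) rows in descending score order.

    ``exclude`` is an optional boolean matrix of cells to omit (e.g. known
    training annotations).  Returns the number of rows written.
    """
    mask = np.ones_like(scores, dtype=bool) if exclude is None else ~exclude
    rows, cols = np.nonzero(mask)
    vals = scores[rows, cols]
    order = np.argsort(-vals, kind="stable")
    if top is not None:
        order = order[:top]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("protein\tterm\tscore\n")
        for k in order:
            fh.write(
                f"{proteins.ids[rows[k]]}\t{terms.ids[cols[k]]}\t{vals[k]:.17g}\n"
            )
    return len(order)
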