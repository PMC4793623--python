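"""Reading, validating and writing the three-matrix DTI dataset format.

A dataset is distributed as three tab-delimited labelled matrices:

* an interaction matrix (drugs in rows, protein targets in columns,
  entries 0/1, 1 = experimentally known drug-target interaction),
* a square drug-drug chemical-similarity matrix with values in [0, 1],
* a square target-target sequence-similarity matrix with values in [0, 1].

The loader is strict: label sets must match between the interaction matrix
and the similarity matrices, every cell must parse as a number, and the
similarity matrices must be symmetric.  Errors name the offending labels or
cell so malformed files are diagnosable.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: symmetry tolerance for similarity matrices
SYMMETRY_TOL = 1e-9


class DatasetValidationError(ValueError):
    """A dataset violated a structural invariant (labels, symmetry, range)."""


class DatasetParseError(ValueError):
    """A dataset file could not be parsed; the message carries the position."""


@dataclass
class DTIDataset:
    """In-memory drug-target interaction dataset.

    Attributes
    ----------
    drug_ids, target_ids:
        Ordered unique identifier lists; order is taken from the
        interaction file and is preserved through every downstream step.
    interactions:
        ``(n_drugs, n_targets)`` binary array, 1 = known interaction.
    drug_sim, target_sim:
        Square symmetric similarity arrays in ``[0, 1]``, indexed in the
        same order as ``drug_ids`` / ``target_ids``.  Diagonals are
        tolerated at any value because self-similarity never enters the
        interaction graph.
    """

    drug_ids: list[str]
    target_ids: list[str]
    interactions: np.ndarray
    drug_sim: np.ndarray
    target_sim: np.ndarray

    def __post_init__(self) -> None:
        self.interactions = np.asarray(self.interactions, dtype=float)
        self.drug_sim = np.asarray(self.drug_sim, dtype=float)
        self.target_sim = np.asarray(self.target_sim, dtype=float)
        validate_dataset(self)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def n_interactions(self) -> int:
        return int(self.interactions.sum())

    def interaction_pairs(self) -> list[tuple[str, str]]:
        """Known (drug_id, target_id) pairs in row-major matrix order."""
        di, ti = np.nonzero(self.interactions)
        return [(self.drug_ids[i], self.target_ids[j]) for i, j in zip(di, ti)]

    def drug_index(self, drug_id: str) -> int:
        try:
            return self.drug_ids.index(drug_id)
        except ValueError:
            raise KeyError(f"unknown drug identifier: {drug_id!r}") from None

    def target_index(self, target_id: str) -> int:
        try:
            return self.target_ids.index(target_id)
        except ValueError:
            raise KeyError(f"unknown target identifier: {target_id!r}") from None


@dataclass
class PredictionRecord:
    """One ranked drug-target prediction.

    ``rank`` is the rank of this target among all targets for the drug
    (1 = highest score); ``known`` flags pairs already present in the
    input interaction matrix.
    """

    drug_id: str
    target_id: str
    score: float
    rank: int
    known: bool = False

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError(f"rank must be >= 1, got {self.rank}")
        if self.score < 0:
            raise ValueError(f"score must be nonnegative, got {self.score}")


def validate_dataset(ds: DTIDataset) -> None:
    """Check all structural invariants, raising ``DatasetValidationError``."""
    nd, nt = len(ds.drug_ids), len(ds.target_ids)
    if len(set(ds.drug_ids)) != nd:
        raise DatasetValidationError("duplicate drug identifiers")
    if len(set(ds.target_ids)) != nt:
        raise DatasetValidationError("duplicate target identifiers")
    if ds.interactions.shape != (nd, nt):
        raise DatasetValidationError(
            f"interaction matrix shape {ds.interactions.shape} does not match "
            f"({nd} drugs, {nt} targets)"
        )
    if not np.isin(ds.interactions, (0.0, 1.0)).all():
        bad = ds.interactions[~np.isin(ds.interactions, (0.0, 1.0))][0]
        raise DatasetValidationError(
            f"interaction matrix must be binary; found value {bad!r}"
        )
    for name, sim, n in (
        ("drug_sim", ds.drug_sim, nd),
        ("target_sim", ds.target_sim, nt),
    ):
        if sim.shape != (n, n):
            raise DatasetValidationError(
                f"{name} has shape {sim.shape}, expected ({n}, {n})"
            )
        if not np.isfinite(sim).all():
            raise DatasetValidationError(f"{name} contains non-finite values")
        if sim.min() < 0.0 or sim.max() > 1.0:
            raise DatasetValidationError(
                f"{name} values must lie in [0, 1]; found "
                f"min={sim.min():g}, max={sim.max():g}"
            )
        asym = np.abs(sim - sim.T).max() if n else 0.0
        if asym > SYMMETRY_TOL:
            i, j = np.unravel_index(np.argmax(np.abs(sim - sim.T)), sim.shape)
            raise DatasetValidationError(
                f"{name} is asymmetric beyond tolerance {SYMMETRY_TOL:g} "
                f"(max deviation {asym:g} at position ({i}, {j}))"
            )


def _read_labelled_matrix(path: str | Path, what: str) -> pd.DataFrame:
    """Read one tab-delimited matrix with a header row and a label column."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    # convert cell by cell so the error can point at the exact position
    values = np.empty(df.shape, dtype=float)
    for i, row in enumerate(df.itertuples(index=False, name=None)):
        for j, cell in enumerate(row):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise DatasetParseError(
                    f"{what} file {path}: non-numeric cell {cell!r} at "
                    f"row {df.index[i]!r}, column {df.columns[j]!r}"
                ) from None
    return pd.DataFrame(values, index=df.index, columns=df.columns)


def _reindex_similarity(
    sim: pd.DataFrame, ids: Sequence[str], what: str
) -> np.ndarray:
    have_rows, have_cols = set(sim.index), set(sim.columns)
    want = set(ids)
    if have_rows != want or have_cols != want:
        missing = sorted(want - (have_rows & have_cols))
        extra = sorted((have_rows | have_cols) - want)
        parts = []
        if missing:
            parts.append(f"missing: {', '.join(missing[:10])}")
        if extra:
            parts.append(f"extra: {', '.join(extra[:10])}")
        raise DatasetValidationError(
            f"{what} labels do not match the interaction file ({'; '.join(parts)})"
        )
    return sim.loc[list(ids), list(ids)].to_numpy()


def load_dataset(
    interaction_path: str | Path,
    drug_sim_path: str | Path,
    target_sim_path: str | Path,
) -> DTIDataset:
    """Load and validate a three-file dataset.

    Drugs are expected in the rows of the interaction matrix; if its labels
    only match the similarity files in the transposed orientation the
    matrix is transposed (and the transposition logged).  Similarity
    matrices are re-indexed to the interaction file's label order, so a
    consistent but permuted distribution loads into an identical dataset.
    """
    inter = _read_labelled_matrix(interaction_path, "interaction")
    dsim = _read_labelled_matrix(drug_sim_path, "drug similarity")
    tsim = _read_labelled_matrix(target_sim_path, "target similarity")

    rows, cols = set(inter.index), set(inter.columns)
    drug_labels = set(dsim.index) | set(dsim.columns)
    target_labels = set(tsim.index) | set(tsim.columns)
    if not (rows <= drug_labels) and rows <= target_labels and cols <= drug_labels:
        logger.info(
            "interaction matrix %s appears target x drug; transposing",
            interaction_path,
        )
        inter = inter.T

    drug_ids = [str(x) for x in inter.index]
    target_ids = [str(x) for x in inter.columns]
    return DTIDataset(
        drug_ids=drug_ids,
        target_ids=target_ids,
        interactions=inter.to_numpy(),
        drug_sim=_reindex_similarity(dsim, drug_ids, "drug similarity"),
        target_sim=_reindex_similarity(tsim, target_ids, "target similarity"),
    )


def write_dataset(
    ds: DTIDataset,
    interaction_path: str | Path,
    drug_sim_path: str | Path,
    target_sim_path: str | Path,
) -> None:
    """Write a dataset in the same three-file format ``load_dataset`` reads."""
    pd.DataFrame(
        ds.interactions.astype(int), index=ds.drug_ids, columns=ds.target_ids
    ).to_csv(interaction_path, sep="\t")
    pd.DataFrame(ds.drug_sim, index=ds.drug_ids, columns=ds.drug_ids).to_csv(
        drug_sim_path, sep="\t", float_format="%.10g"
    )
    pd.DataFrame(ds.target_sim, index=ds.target_ids, columns=ds.target_ids).to_csv(
        target_sim_path, sep="\t", float_format="%.10g"
    )


PREDICTION_COLUMNS = ("drug_id", "target_id", "score", "rank", "known")


def write_predictions(
    records: Sequence[PredictionRecord], path: str | Path | io.TextIOBase
) -> None:
    """Write ranked predictions as a tab-separated table.

    Rows are sorted by drug identifier, then rank; scores are printed with
    enough digits to round-trip typical path scores.
    """
    if not records:
        raise ValueError("no prediction records to write")
    ordered = sorted(records, key=lambda r: (r.drug_id, r.rank))
    df = pd.DataFrame(
        [
            (r.drug_id, r.target_id, r.score, r.rank, r.known)
            for r in ordered
        ],
        columns=list(PREDICTION_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_predictions(path: str | Path) -> list[PredictionRecord]:
    """Parse a file written by :func:`write_predictions`."""
    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "target_id": str})
    return [
        PredictionRecord(
            drug_id=row.drug_id,
            target_id=row.target_id,
            score=float(row.score),
            rank=int(row.rank),
            known=bool(row.known),
        )
        for row in df.itertuples(index=False)
    ]
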