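"""CSV readers/writers and the packaged tables of the case study.

The on-disk dialect is deliberately plain: comma-separated, UTF-8, ``.``
decimal separator, one header row, first column = alternative id. A
*directions sidecar* (``criterion_id,direction``) declares which criteria
are benefit- and which cost-oriented. Writers can embed a provenance
header (``# key: json``) so every output records the configuration that
produced it; readers skip ``#`` lines.

The packaged fixtures transcribe the printed result tables of the OAS
transport-safety case study: composite scores/ranks for two years
(``table1_scores``), six-way country groups (``table2_groups``), and rank
columns under alternate normalizations, weightings and aggregators
(``table3_norm_ranks``, ``table4_weight_ranks``, ``table5_agg_ranks``).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import (
    BENEFIT,
    COST,
    CriterionSpec,
    DecisionMatrix,
    GroupingResult,
    RankVector,
    ScoreTable,
    WeightVector,
)
from .errors import (
    DuplicateIdError,
    MissingDirectionError,
    NonNumericCellError,
    UnknownMethodError,
    ValidationError,
)

FIXTURE_NAMES = (
    "table1_scores",
    "table2_groups",
    "table3_norm_ranks",
    "table4_weight_ranks",
    "table5_agg_ranks",
)

_YEARS = ("2010", "2020")


# ---------------------------------------------------------------- reading

def _read_rows(path: str | Path) -> list[list[str]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        return [row for row in csv.reader(fh) if row and not row[0].startswith("#")]


def _direction_mapping(directions) -> dict[str, str]:
    if isinstance(directions, (str, Path)):
        rows = _read_rows(directions)
        if rows and rows[0][:2] == ["criterion_id", "direction"]:
            rows = rows[1:]
        mapping = {}
        for row in rows:
            if len(row) < 2:
                raise ValidationError(f"malformed directions row: {row!r}")
            mapping[row[0]] = row[1]
        return mapping
    return dict(directions)


def read_decision_matrix(path: str | Path, directions=None) -> DecisionMatrix:
    """Read an alternatives-by-criteria CSV into a validated DecisionMatrix.

    ``directions`` is a mapping ``{criterion_id: "benefit"|"cost"}`` or the
    path of a sidecar CSV; it must cover every criterion in the header.
    When ``None``, every criterion defaults to benefit.
    """
    rows = _read_rows(path)
    if not rows:
        raise ValidationError(f"empty file: {path}")
    header = rows[0]
    crit_ids = [h.strip() for h in header[1:]]
    if len(set(crit_ids)) != len(crit_ids):
        raise DuplicateIdError("duplicate criterion id in header")
    mapping = _direction_mapping(directions) if directions is not None else {}
    for cid in crit_ids:
        d = mapping.get(cid, BENEFIT if directions is None else None)
        if d is None:
            raise MissingDirectionError(f"no direction for criterion {cid!r}")
        if d not in (BENEFIT, COST):
            raise ValidationError(f"bad direction {d!r} for criterion {cid!r}")
    criteria = [
        CriterionSpec(cid, mapping.get(cid, BENEFIT)) for cid in crit_ids
    ]
    alts: list[str] = []
    values: list[list[float]] = []
    for row in rows[1:]:
        if len(row) != len(header):
            raise ValidationError(f"row length mismatch: {row!r}")
        alts.append(row[0].strip())
        vals = []
        for cell, cid in zip(row[1:], crit_ids):
            try:
                vals.append(float(cell))
            except ValueError as exc:
                raise NonNumericCellError(
                    f"non-numeric cell {cell!r} (alternative {row[0]!r}, "
                    f"criterion {cid!r})"
                ) from exc
        values.append(vals)
    if len(set(alts)) != len(alts):
        dup = next(a for a in alts if alts.count(a) > 1)
        raise DuplicateIdError(f"duplicate alternative id {dup!r}")
    return DecisionMatrix(alts, criteria, values)


# ---------------------------------------------------------------- fixtures

def fixture_frame(name: str) -> pd.DataFrame:
    """Return a packaged fixture as the raw DataFrame (index = country)."""
    if name not in FIXTURE_NAMES:
        raise UnknownMethodError(
            f"unknown fixture {name!r}; known: {', '.join(FIXTURE_NAMES)}"
        )
    ref = resources.files("graphmcdm.fixtures").joinpath(f"{name}.csv")
    with resources.as_file(ref) as p:
        return pd.read_csv(p, index_col=0)


@dataclass(frozen=True)
class ScoreFixture:
    """Printed composite scores plus the printed rank columns, per year."""

    matrix: DecisionMatrix  # criteria: score_2010, score_2020 (benefit)
    ranks: dict[str, RankVector]


def load_fixture(name: str):
    """Load a packaged printed table.

    Returns a :class:`ScoreFixture` for ``table1_scores``, a
    ``{year: ndarray}`` label mapping (plus ``"countries"``) for
    ``table2_groups``, and a ``{column: RankVector}`` mapping for the
    rank-contrast tables 3-5.
    """
    df = fixture_frame(name)
    countries = tuple(df.index)
    if name == "table1_scores":
        matrix = DecisionMatrix(
            countries,
            [CriterionSpec(f"score_{y}", BENEFIT) for y in _YEARS],
            df[[f"score_{y}" for y in _YEARS]].to_numpy(),
        )
        ranks = {
            y: RankVector(countries, df[f"rank_{y}"].to_numpy(), source=f"waspas_{y}")
            for y in _YEARS
        }
        return ScoreFixture(matrix, ranks)
    if name == "table2_groups":
        out = {y: df[f"group_{y}"].to_numpy() for y in _YEARS}
        out["countries"] = countries
        return out
    return {
        col: RankVector(countries, df[col].to_numpy(), source=col)
        for col in df.columns
    }


# ---------------------------------------------------------------- writing

def _write_frame(df: pd.DataFrame, path: str | Path, provenance: Mapping | None,
                 index: bool) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if provenance:
            fh.write("# config: " + json.dumps(dict(provenance), sort_keys=True) + "\n")
        df.to_csv(fh, index=index, float_format="%.17g")


def score_table_frame(st: ScoreTable) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "alternative": st.alternatives,
            "ws": st.ws,
            "wp": st.wp,
            "wq": st.wq,
            "rank": st.rank,
            "lambda": st.lam,
        }
    )


def write_score_table(st: ScoreTable, path, provenance=None) -> None:
    _write_frame(score_table_frame(st), path, provenance, index=False)


def read_score_table(path) -> ScoreTable:
    df = pd.read_csv(path, comment="#")
    return ScoreTable(
        tuple(df["alternative"].astype(str)),
        df["ws"].to_numpy(),
        df["wp"].to_numpy(),
        df["wq"].to_numpy(),
        df["rank"].to_numpy(),
        float(df["lambda"].iloc[0]),
    )


def write_weights(w: WeightVector, path, provenance=None) -> None:
    ids = w.criterion_ids or tuple(f"c{j+1}" for j in range(len(w)))
    df = pd.DataFrame({"criterion_id": ids, "weight": w.weights, "method": w.method})
    _write_frame(df, path, provenance, index=False)


def read_weights(path) -> WeightVector:
    df = pd.read_csv(path, comment="#")
    return WeightVector(
        df["weight"].to_numpy(),
        str(df["method"].iloc[0]),
        tuple(df["criterion_id"].astype(str)),
    )


def write_grouping(result: GroupingResult, alternatives, path, provenance=None) -> None:
    df = pd.DataFrame({"alternative_id": list(alternatives), "label": result.labels})
    _write_frame(df, path, provenance, index=False)


def read_grouping(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_rank_vector(rv: RankVector, path, provenance=None) -> None:
    df = pd.DataFrame(
        {"alternative": rv.alternatives, "rank": rv.ranks, "source": rv.source}
    )
    _write_frame(df, path, provenance, index=False)


def write_decision_matrix(X: DecisionMatrix, path, directions_path=None,
                          provenance=None) -> None:
    df = pd.DataFrame(X.values, index=list(X.alternatives),
                      columns=list(X.criterion_ids))
    df.index.name = "alternative"
    _write_frame(df, path, provenance, index=True)
    if directions_path is not None:
        sidecar = pd.DataFrame(
            {"criterion_id": X.criterion_ids, "direction": X.directions}
        )
        _write_frame(sidecar, directions_path, None, index=False)


def write_matrix_csv(labels, matrix: np.ndarray, path, provenance=None) -> None:
    """Write a square labelled matrix (e.g. pairwise rho / V-measure)."""
    df = pd.DataFrame(np.asarray(matrix, dtype=float), index=list(labels),
                      columns=list(labels))
    df.index.name = "variant"
    _write_frame(df, path, provenance, index=True)


def read_matrix_csv(path):
    df = pd.read_csv(path, comment="#", index_col=0)
    return tuple(df.index), df.to_numpy()
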