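"""File round-tripping and the end-to-end pipeline runner.

The on-disk schema is deliberately plain: a UTF-8 CSV with one or more
grouping columns followed by one column per question, one respondent per
row, answers treated as opaque categorical strings. Distance matrices are
labelled square CSVs (radians, repr precision); reports are JSON.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .estimators import FisherInformationEmbedding
from .exceptions import QManifoldError, SchemaMismatchError
from .geometry import DistanceMatrix
from .embedding import scree
from .responses import ResponseTable, validate_table
from .simulate import CurveSpec, simulate_study

__all__ = ["RunConfig", "read_responses", "write_responses", "run_pipeline"]

#: joins levels of multiple grouping columns into one composite label
_GROUP_SEP = "/"


def read_responses(
    path,
    group_columns: str | Sequence[str] = "group",
    questions: Sequence[str] | None = None,
    alphabets: dict[str, Sequence[str]] | None = None,
) -> ResponseTable:
    """Read a response CSV into a :class:`ResponseTable`.

    With several ``group_columns`` the grouping is their cross-product
    (e.g. ethnicity x smoking status), with composite labels joined by
    ``"/"``. ``questions`` defaults to every non-grouping column;
    ``alphabets`` pins answer dimensions when supplied.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise QManifoldError(f"{path}: file is empty") from None
    if df.empty:
        raise QManifoldError(f"{path}: no respondent rows")
    group_columns = [group_columns] if isinstance(group_columns, str) else list(group_columns)
    missing = [c for c in group_columns if c not in df.columns]
    if missing:
        raise SchemaMismatchError(f"{path}: missing group column(s) {missing}")
    if questions is None:
        questions = [c for c in df.columns if c not in group_columns]
    ragged = df[questions].isin(("",)).any(axis=1)
    if ragged.any():
        rows = [int(r) + 2 for r in np.flatnonzero(ragged.to_numpy())]  # 1-based + header
        raise QManifoldError(f"{path}: ragged/empty answer cells at rows {rows}")
    groups = df[group_columns[0]].astype(str)
    for col in group_columns[1:]:
        groups = groups + _GROUP_SEP + df[col].astype(str)
    return ResponseTable(
        answers=df[list(questions)],
        groups=groups.rename("group"),
        alphabets=alphabets,
    )


def write_responses(table: ResponseTable, path, group_column: str = "group") -> None:
    """Write a response table to CSV (inverse of :func:`read_responses`)."""
    df = table.answers.copy()
    df.insert(0, group_column, table.groups.values)
    df.to_csv(path, index=False)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` (a response CSV) or ``sim`` (a simulation
    spec plus sampling sizes) must be given.
    """

    out_dir: str
    input_path: str | None = None
    group_columns: tuple[str, ...] = ("group",)
    sim: CurveSpec | None = None
    sim_groups: int = 20
    sim_n_per_group: int = 25
    sim_placement: str = "uniform"
    alpha: float = 0.0
    dimension: int | str = 2  # int or "auto" (scree elbow)
    style: str = "default"  # "default" | "subak" (full-rank MDS then PCA to 2)
    seed: int | None = None
    min_group_size: int = 20

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.sim is None):
            raise ValueError("exactly one of input_path / sim must be set")
        if self.style not in ("default", "subak"):
            raise ValueError("style must be 'default' or 'subak'")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run estimate -> Fisher distances -> MDS (-> PCA) and write artifacts.

    Writes, under ``config.out_dir``: ``distances.csv`` (Fisher distance
    matrix, radians), ``embedding.csv`` (group coordinates),
    ``scree.json`` (spectrum and elbow suggestion), ``run_log.json``
    (config echo, versions, seed, string-order convention) and, for
    simulated input, ``responses.csv`` plus the theoretical
    ``distances_theoretical.csv``. Identical configs yield identical bytes
    apart from the log timestamp. Partially written outputs are removed on
    failure.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        artifacts: dict[str, Path] = {}
        stage = "load"
        if config.sim is not None:
            study = simulate_study(
                config.sim,
                config.sim_groups,
                config.sim_n_per_group,
                config.sim_placement,
                config.seed,
            )
            table = study.table
            p = out / "responses.csv"
            write_responses(table, p)
            written.append(p)
            artifacts["responses"] = p
            p = out / "distances_theoretical.csv"
            study.theoretical_distances().to_csv(p)
            written.append(p)
            artifacts["distances_theoretical"] = p
            p = out / "ground_truth.json"
            p.write_text(json.dumps({
                "t_values": list(study.t_values),
                "placement": study.placement,
            }, indent=2))
            written.append(p)
            artifacts["ground_truth"] = p
        else:
            table = read_responses(config.input_path, list(config.group_columns))

        stage = "estimate+embed"
        est = FisherInformationEmbedding(
            n_components=2 if config.style == "subak" else config.dimension,
            alpha=config.alpha,
            pca_components=2 if config.style == "subak" else None,
        )
        est.fit(table)

        stage = "write"
        p = out / "distances.csv"
        est.distance_matrix_.to_csv(p)
        written.append(p)
        artifacts["distances"] = p

        p = out / "embedding.csv"
        cols = [f"dim{i + 1}" for i in range(est.embedding_.shape[1])]
        pd.DataFrame(est.embedding_, index=est.labels_, columns=cols).to_csv(
            p, float_format="%.17g"
        )
        written.append(p)
        artifacts["embedding"] = p

        report = scree(est.eigenvalues_)
        p = out / "scree.json"
        p.write_text(json.dumps({
            "eigenvalues": [float(v) for v in est.eigenvalues_],
            "positive_eigenvalues": [float(v) for v in report.eigenvalues],
            "cumulative_share": [float(v) for v in report.cumulative_share],
            "suggestion": report.suggestion,
            "flat": report.flat,
        }, indent=2))
        written.append(p)
        artifacts["scree"] = p

        summary = validate_table(table, config.min_group_size)
        p = out / "run_log.json"
        p.write_text(json.dumps({
            "qmanifold_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "seed": config.seed,
            "alpha": config.alpha,
            "dimension_requested": config.dimension,
            "dimension_used": est.n_components_,
            "variance_retained": est.variance_retained_,
            "style": config.style,
            "string_order": "lexicographic-v1 (question 1 most significant)",
            "n_groups": len(est.labels_),
            "small_groups": summary.small_groups,
        }, indent=2))
        written.append(p)
        artifacts["run_log"] = p
        return artifacts
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise QManifoldError(f"pipeline failed at stage {stage!r}: {exc}") from exc
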