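"""File formats: instrument summaries, result tables, synthetic fixtures.

Instrument files come in two forms:

* a single JSON document::

    {"schema_version": 1,
     "dimensions": [{"name": "A", "alpha": 0.84, "n_items": 5}, ...],
     "composite_corr": {"names": ["A", "B"], "values": [[1.0, 0.4], [0.4, 1.0]]}}

* a pair of CSVs: a dimensions table (columns name, alpha, n_items) and a
  correlation matrix with a header row and a leading label column.

Matrix validation tolerates asymmetry up to 1e-6; after validation the
matrix is symmetrized by averaging.  Result writers emit CSV (6 significant
digits) or JSON (full precision); everything the package writes its own
readers accept back.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cfa import FactorModel, sample_dataset
from .criteria import (
    DimensionSummary,
    InstrumentSummary,
    LoadingSet,
    PairAssessment,
    assess_instrument,
    standardized_alpha,
)
from .errors import InvalidInputError, ValidationError
from .simulation import CellResult, _pattern_pair, population_decision_curve, results_to_frame

__all__ = [
    "read_instrument",
    "write_instrument",
    "write_results",
    "read_cell_results",
    "generate_fixture",
]

SCHEMA_VERSION = 1
_SYM_TOL = 1e-6


def _validate_matrix(values, names) -> np.ndarray:
    m = np.asarray(values, dtype=float)
    details = []
    d = len(names)
    if m.shape != (d, d):
        raise ValidationError(
            f"composite_corr must be {d}x{d} to match the dimensions", []
        )
    for i in range(d):
        if abs(m[i, i] - 1.0) > _SYM_TOL:
            details.append(f"diagonal entry ({names[i]}, {names[i]}) = {m[i, i]!r}, expected 1")
    for i in range(d):
        for j in range(i + 1, d):
            if abs(m[i, j] - m[j, i]) > _SYM_TOL:
                details.append(
                    f"asymmetric pair ({names[i]}, {names[j]}): "
                    f"{m[i, j]!r} vs {m[j, i]!r}"
                )
            if abs(m[i, j]) > 1.0 + _SYM_TOL:
                details.append(f"entry ({names[i]}, {names[j]}) = {m[i, j]!r} outside [-1, 1]")
    if details:
        raise ValidationError("invalid composite correlation matrix", details)
    m = (m + m.T) / 2.0  # symmetrize after validation passes
    np.fill_diagonal(m, 1.0)
    return np.clip(m, -1.0, 1.0)


def _build_instrument(dim_rows, names, values) -> InstrumentSummary:
    details = []
    dims = []
    for row in dim_rows:
        try:
            dims.append(
                DimensionSummary(
                    name=str(row["name"]),
                    alpha=float(row["alpha"]),
                    n_items=int(row["n_items"]),
                )
            )
        except (InvalidInputError, KeyError, TypeError, ValueError) as exc:
            details.append(f"dimension {row.get('name', '?')!r}: {exc}")
    if details:
        raise ValidationError("invalid dimension table", details)
    dim_names = [d.name for d in dims]
    if list(names) != dim_names:
        raise ValidationError(
            "matrix labels must match dimension names exactly and in order",
            [f"matrix labels {list(names)!r} vs dimensions {dim_names!r}"],
        )
    matrix = _validate_matrix(values, dim_names)
    return InstrumentSummary(dimensions=tuple(dims), composite_corr=matrix)


def read_instrument(path, matrix_path=None) -> InstrumentSummary:
    """Read an instrument summary from JSON, or from a CSV pair.

    With one argument, ``path`` is the JSON document; with two, ``path`` is
    the dimensions CSV and ``matrix_path`` the labelled correlation-matrix
    CSV.
    """
    path = Path(path)
    if matrix_path is None:
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("schema_version") != SCHEMA_VERSION:
            raise ValidationError(
                f"unsupported schema_version {doc.get('schema_version')!r}", []
            )
        cc = doc["composite_corr"]
        return _build_instrument(doc["dimensions"], cc["names"], cc["values"])
    dims_df = pd.read_csv(path)
    missing = {"name", "alpha", "n_items"} - set(dims_df.columns)
    if missing:
        raise ValidationError(f"dimensions CSV lacks columns {sorted(missing)}", [])
    mat_df = pd.read_csv(matrix_path, index_col=0)
    if list(mat_df.index.astype(str)) != list(mat_df.columns.astype(str)):
        raise ValidationError(
            "matrix CSV row labels must equal its column labels",
            [f"rows {list(mat_df.index)!r} vs columns {list(mat_df.columns)!r}"],
        )
    return _build_instrument(
        dims_df.to_dict("records"), list(mat_df.columns.astype(str)), mat_df.to_numpy()
    )


def write_instrument(instr: InstrumentSummary, path) -> Path:
    """Write an instrument summary as a schema-versioned JSON document."""
    path = Path(path)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "dimensions": [
            {"name": d.name, "alpha": d.alpha, "n_items": d.n_items}
            for d in instr.dimensions
        ],
        "composite_corr": {
            "names": list(instr.names),
            "values": instr.composite_corr.tolist(),
        },
    }
    path.write_text(json.dumps(doc, indent=2) + "\n")
    return path


def _assessments_frame(assessments: Sequence[PairAssessment]) -> pd.DataFrame:
    cols = [f.name for f in dataclasses.fields(PairAssessment)]
    rows = []
    for a in assessments:
        d = dataclasses.asdict(a)
        d["pair"] = f"{a.pair[0]}|{a.pair[1]}"
        rows.append(d)
    return pd.DataFrame(rows, columns=cols)


def write_results(results, path, format: str = "csv") -> Path:
    """Write pair assessments or simulation cell results to CSV or JSON.

    CSV rounds floats to 6 significant digits; JSON keeps full precision
    (re-reading JSON reproduces every value to better than 1e-12).  Field
    order is deterministic.  An empty list produces a header-only file.
    """
    path = Path(path)
    results = list(results)
    if results and isinstance(results[0], CellResult):
        frame = results_to_frame(results)
    elif all(isinstance(r, PairAssessment) for r in results):
        frame = _assessments_frame(results)
    else:
        raise InvalidInputError(
            "results must be PairAssessment or CellResult objects (uniformly)"
        )
    if format == "csv":
        frame.to_csv(path, index=False, float_format="%.6g")
    elif format == "json":
        path.write_text(
            json.dumps(frame.to_dict("records"), indent=2, default=_json_default) + "\n"
        )
    else:
        raise InvalidInputError(f"format must be 'csv' or 'json', got {format!r}")
    return path


def _json_default(obj):
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_cell_results(path) -> pd.DataFrame:
    """Read back a long-format simulation results file (CSV or JSON)."""
    path = Path(path)
    if path.suffix == ".json":
        return pd.DataFrame(json.loads(path.read_text()))
    return pd.read_csv(path)


def generate_fixture(
    kind: str,
    phi: float,
    n: int,
    seed: int,
    out_dir,
    pattern=None,
    dimension_names: tuple[str, str] = ("X", "Y"),
) -> dict:
    """Simulate one two-dimension dataset and write a fixture bundle.

    ``kind`` selects the default loading pattern: ``tau_equivalent`` (equal
    0.70 loadings) or ``congeneric`` (0.60/0.70/0.80); pass ``pattern`` to
    override.  Writes into ``out_dir``:

    * ``instrument.json`` — sample alphas, item counts, and the sample
      composite correlation in the instrument schema;
    * ``data.csv`` — the simulated indicator matrix;
    * ``provenance.json`` — generating parameters plus the instrument's
      true population verdict for the chosen phi.

    Deterministic given ``seed``; returns the paths, the instrument summary
    and the population verdict.
    """
    if pattern is None:
        if kind == "tau_equivalent":
            pattern = (0.70, 0.70, 0.70)
        elif kind == "congeneric":
            pattern = (0.60, 0.70, 0.80)
        else:
            raise InvalidInputError(
                f"kind must be 'tau_equivalent' or 'congeneric', got {kind!r}"
            )
    lx, ly = _pattern_pair(pattern)
    model = FactorModel(lx, ly, phi)
    kx, ky = model.n_indicators

    data = sample_dataset(model, n, seed)
    r_full = np.corrcoef(data, rowvar=False)
    alpha_x = standardized_alpha(r_full[:kx, :kx])
    alpha_y = standardized_alpha(r_full[kx:, kx:])
    r_comp = float(
        np.corrcoef(data[:, :kx].mean(axis=1), data[:, kx:].mean(axis=1))[0, 1]
    )
    nx, ny = dimension_names
    instr = InstrumentSummary(
        dimensions=(
            DimensionSummary(nx, alpha_x, kx),
            DimensionSummary(ny, alpha_y, ky),
        ),
        composite_corr=np.array([[1.0, r_comp], [r_comp, 1.0]]),
    )

    curve = population_decision_curve(pattern, phi_grid_hundredths=[round(phi * 100)])
    row = curve.iloc[0]
    if row.double_met:
        population_verdict = "distinct_certain"
    elif row.single_met:
        population_verdict = "uncertain"
    else:
        population_verdict = "violation_certain"

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    instr_path = write_instrument(instr, out_dir / "instrument.json")
    data_path = out_dir / "data.csv"
    header = [f"{nx.lower()}{i + 1}" for i in range(kx)] + [
        f"{ny.lower()}{i + 1}" for i in range(ky)
    ]
    pd.DataFrame(data, columns=header).to_csv(data_path, index=False, float_format="%.8g")
    prov_path = out_dir / "provenance.json"
    prov_path.write_text(
        json.dumps(
            {
                "kind": kind,
                "loadings_x": lx.loadings.tolist(),
                "loadings_y": ly.loadings.tolist(),
                "phi": phi,
                "n": n,
                "seed": seed,
                "population_verdict": population_verdict,
            },
            indent=2,
        )
        + "\n"
    )
    return {
        "instrument": instr,
        "population_verdict": population_verdict,
        "paths": {"instrument": instr_path, "data": data_path, "provenance": prov_path},
    }
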