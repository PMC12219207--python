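"""Packaged study data: the 22 dry-eye-disease drugs.

The published study tables ship with the package as plain CSV/JSON so every
stage of the pipeline can be exercised against the exact printed numbers:

* ``properties.csv`` -- seven physicochemical properties per drug (boiling
  point, molar refractivity, polarizability, molar volume, enthalpy of
  vaporization, complexity, molecular weight).  Missing cells are printed as a
  dash in the source and encoded here with the explicit sentinel ``NA``.
* ``indices.csv`` -- the eleven degree-based topological index values per
  drug, transcribed verbatim.  Some printed rows violate the exact identity
  ``HM = F + 2*M2``; they are *flagged*, never edited
  (:func:`validate_index_table`), so downstream results are reproducible
  against the source as published.
* ``models.json`` -- the seven published regression models (regressor sets,
  printed coefficients and fit statistics), used as reference values when
  refitting.
* ``diclofenac_edges.txt`` -- the hydrogen-suppressed molecular graph of
  Diclofenac (19 heavy atoms, 20 bonds), the study's worked example and the
  only structure published as a graph.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .molgraph import EdgePartition, MolecularGraph, graph_from_edge_list
from .qspr import ModelSpec

__all__ = [
    "PROPERTY_UNITS",
    "load_property_table",
    "load_index_table",
    "validate_index_table",
    "serialize_table",
    "load_model_specs",
    "diclofenac_graph",
    "diclofenac_partition",
]

PROPERTY_UNITS = {
    "BP": "degC",  # boiling point at 760 mmHg
    "MR": "cm^3",  # molar refractivity
    "P": "1e-24 cm^3",  # polarizability
    "MV": "cm^3",  # molar volume
    "E": "kJ/mol",  # enthalpy of vaporization
    "C": "",  # complexity (unitless)
    "MW": "g/mol",  # molecular weight
}

_EXPECTED_ROWS = 22


def _read_text(name: str) -> str:
    ref = resources.files("tiqspr.data").joinpath(name)
    try:
        return ref.read_text(encoding="utf-8")
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"packaged fixture {name!r} is missing") from exc


def _read_csv(name: str) -> pd.DataFrame:
    from io import StringIO

    df = pd.read_csv(
        StringIO(_read_text(name)),
        index_col="drug",
        na_values=["NA"],
        keep_default_na=False,
    )
    if len(df) != _EXPECTED_ROWS:
        raise ValueError(f"fixture {name!r} is corrupted: expected {_EXPECTED_ROWS} rows, found {len(df)}")
    return df


def load_property_table() -> pd.DataFrame:
    """The 22 x 7 physicochemical property table, units in ``.attrs['units']``.

    Five cells are missing in the source (Lifitegrast BP, Pranoprofen P,
    Cyclosporine E, Minocycline C and MW) and come back as NaN.
    """
    df = _read_csv("properties.csv")
    if list(df.columns) != list(PROPERTY_UNITS):
        raise ValueError("fixture properties.csv is corrupted: unexpected columns")
    df.attrs["units"] = dict(PROPERTY_UNITS)
    return df


def load_index_table() -> pd.DataFrame:
    """The 22 x 11 topological-index table, verbatim as published.

    The identity-violation report is attached as
    ``.attrs['identity_violations']`` (see :func:`validate_index_table`).
    """
    df = _read_csv("indices.csv")
    if df.isna().any().any():
        raise ValueError("fixture indices.csv is corrupted: missing cells")
    df.attrs["identity_violations"] = validate_index_table(df)
    return df


def validate_index_table(table: pd.DataFrame) -> pd.Series:
    """Per-drug deviation ``HM - F - 2*M2`` for rows violating the exact
    identity; empty when the table is internally consistent.

    Violations are reported, never corrected: they are evidence about the
    published table, and downstream analyses run on the published numbers.
    """
    dev = table["HM"] - table["F"] - 2 * table["M2"]
    return dev[dev != 0].rename("HM - F - 2*M2")


def serialize_table(df: pd.DataFrame) -> str:
    """Serialise a fixture table back to the packaged CSV dialect.

    Shortest decimal representation per cell and the ``NA`` sentinel for
    missing values, so ``serialize_table(load_*_table())`` round-trips the
    packaged file byte for byte.
    """
    lines = ["drug," + ",".join(df.columns)]
    for drug, row in df.iterrows():
        cells = ["NA" if pd.isna(v) else format(v, "g") for v in row]
        lines.append(f"{drug}," + ",".join(cells))
    return "\n".join(lines) + "\n"


def load_model_specs() -> dict[int, ModelSpec]:
    """The seven published regression model specifications keyed by model id."""
    raw = json.loads(_read_text("models.json"))
    specs = {}
    for entry in raw:
        spec = ModelSpec(
            model_id=entry["id"],
            response=entry["response"],
            regressors=tuple(entry["regressors"]),
            printed_intercept=entry["intercept"],
            printed_coefficients=dict(entry["coefficients"]),
            printed_stats={
                k: entry[k] for k in ("n", "r", "R2", "SE", "F", "RMSE", "p")
            },
        )
        specs[spec.model_id] = spec
    return specs


def diclofenac_graph() -> MolecularGraph:
    """The Diclofenac heavy-atom graph (19 vertices, 20 edges)."""
    return graph_from_edge_list(_read_text("diclofenac_edges.txt"))


def diclofenac_partition() -> EdgePartition:
    """The published Diclofenac edge partition:
    ``{(1,3): 4, (2,2): 5, (2,3): 8, (3,3): 3}``."""
    return EdgePartition({(1, 3): 4, (2, 2): 5, (2, 3): 8, (3, 3): 3})
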