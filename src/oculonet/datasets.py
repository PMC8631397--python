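"""Packaged reference correlation tables and the simulation target matrix.

Three published correlation tables for the patient cohort ship with the
package as plain CSV fixtures:

* ``table5_cognitive.csv`` — pairwise correlations among the six
  cognitive sub-tests (symmetric, upper triangle printed);
* ``table6_oculomotor.csv`` — pairwise correlations among the six
  oculomotor summary measures (symmetric);
* ``table7_cross.csv`` — rectangular cognitive x oculomotor block.

Each row carries ``row_label, col_label, r, sig_code`` where ``sig_code``
is one of ``ns, .1, .05, .01, .001`` (the nominal p-value ceiling the
printed footnote marker implies).  These tables are both the worked-example
input to the network builder and the calibration target of the cohort
simulator.
"""

from __future__ import annotations

from importlib import resources
from typing import NamedTuple

import numpy as np
import pandas as pd

from .exceptions import FixtureError
from .measures import ALL_MEASURES, COGNITIVE_MEASURES, OCULOMOTOR_MEASURES, SIG_CODES

_FIXTURES = {
    "cognitive": "table5_cognitive.csv",
    "oculomotor": "table6_oculomotor.csv",
    "cross": "table7_cross.csv",
}


class PaperTables(NamedTuple):
    """The three printed correlation tables, as long-form data frames."""

    cognitive: pd.DataFrame
    oculomotor: pd.DataFrame
    cross: pd.DataFrame


def _read_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("oculonet.data").joinpath(name)
    try:
        with ref.open("r") as fh:
            df = pd.read_csv(fh, dtype={"sig_code": str})
    except (FileNotFoundError, pd.errors.ParserError) as exc:
        raise FixtureError(f"cannot load packaged table {name!r}: {exc}") from exc
    expected = {"row_label", "col_label", "r", "sig_code"}
    if set(df.columns) != expected:
        raise FixtureError(
            f"packaged table {name!r} has columns {list(df.columns)}, "
            f"expected {sorted(expected)}"
        )
    bad = set(df["sig_code"]) - set(SIG_CODES)
    if bad:
        raise FixtureError(f"packaged table {name!r} carries unknown codes {bad}")
    if df["r"].abs().gt(1).any():
        raise FixtureError(f"packaged table {name!r} has |r| > 1")
    return df


def load_paper_tables() -> PaperTables:
    """Load the three packaged correlation tables.

    Returns
    -------
    PaperTables
        ``cognitive`` and ``oculomotor`` are the 15-row upper triangles of
        the two symmetric within-domain tables; ``cross`` is the 36-row
        oculomotor x cognitive block.

    Raises
    ------
    FixtureError
        If a fixture file is missing or malformed; the message names it.
    """
    return PaperTables(**{k: _read_fixture(v) for k, v in _FIXTURES.items()})


def _square_from_long(df: pd.DataFrame, labels: tuple[str, ...]) -> pd.DataFrame:
    mat = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for row in df.itertuples():
        mat.loc[row.row_label, row.col_label] = row.r
        mat.loc[row.col_label, row.row_label] = row.r
    return mat


def target_correlation_matrix(tables: PaperTables | None = None) -> pd.DataFrame:
    """Assemble the 12x12 correlation matrix over all measures.

    The cognitive and oculomotor blocks come from the two within-domain
    tables; the off-diagonal block comes from the cross table.  The result
    is symmetric with unit diagonal; it is the simulator's default
    ``target_correlation``.
    """
    if tables is None:
        tables = load_paper_tables()
    mat = pd.DataFrame(
        np.eye(len(ALL_MEASURES)), index=list(ALL_MEASURES), columns=list(ALL_MEASURES)
    )
    cog = _square_from_long(tables.cognitive, COGNITIVE_MEASURES)
    ocu = _square_from_long(tables.oculomotor, OCULOMOTOR_MEASURES)
    mat.loc[list(COGNITIVE_MEASURES), list(COGNITIVE_MEASURES)] = cog.values
    mat.loc[list(OCULOMOTOR_MEASURES), list(OCULOMOTOR_MEASURES)] = ocu.values
    for row in tables.cross.itertuples():
        mat.loc[row.row_label, row.col_label] = row.r
        mat.loc[row.col_label, row.row_label] = row.r
    return mat


def sig_code_table(tables: PaperTables | None = None) -> pd.DataFrame:
    """Square 12x12 table of significance codes (diagonal left empty)."""
    if tables is None:
        tables = load_paper_tables()
    codes = pd.DataFrame(
        "", index=list(ALL_MEASURES), columns=list(ALL_MEASURES), dtype=object
    )
    for df in tables:
        for row in df.itertuples():
            codes.loc[row.row_label, row.col_label] = row.sig_code
            codes.loc[row.col_label, row.row_label] = row.sig_code
    return codes
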