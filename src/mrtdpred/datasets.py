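"""Descriptor datasets: schema, CSV I/O, the bundled ARV table, summaries.

A dataset is a :class:`pandas.DataFrame` with one row per compound and the
columns

``name``
    unique, non-empty compound identifier;
``subset``
    one of ``train`` / ``test`` / ``unassigned``;
``mrtd``
    clinical maximum recommended therapeutic dose in mg/kg/day
    (strictly positive; may be missing for prediction-only inputs);
``oxid_hl, p_bd, log_bio_hl, alogp, asol, mw``
    the six molecular property descriptors, in the canonical order used
    everywhere a descriptor vector is implied:

    ======== ============================================== ==========
    column   meaning                                        units
    ======== ============================================== ==========
    oxid_hl  atmospheric/oxidative half-life (> 0)          days
    p_bd     probability of ready biodegradation            0-1 fraction
    log_bio_hl log10 whole-body biotransformation half-life log10 days
    alogp    computed octanol-water partition coefficient   (dimensionless)
    asol     predicted aqueous solubility (> 0)             g/L
    mw       molecular weight (> 0)                         Da
    ======== ============================================== ==========

P[BD] is stored as a 0-1 fraction throughout (the published table prints
fractions despite a "%" column head).
"""

from __future__ import annotations

import io
from importlib import resources
from typing import IO, Union

import numpy as np
import pandas as pd

#: Canonical descriptor column order.
DESCRIPTOR_COLUMNS = ("oxid_hl", "p_bd", "log_bio_hl", "alogp", "asol", "mw")

#: Numeric columns a CSV source must name (values in ``mrtd`` may be blank).
NUMERIC_COLUMNS = ("mrtd",) + DESCRIPTOR_COLUMNS

SUBSETS = ("train", "test", "unassigned")

PathOrBuffer = Union[str, "io.TextIOBase", IO[str]]


class SchemaError(ValueError):
    """The CSV header does not name the required columns."""


class ParseError(ValueError):
    """A cell could not be parsed as a number."""


class InvariantError(ValueError):
    """A row violates a descriptor or dose invariant."""


def _normalize_minus(text: str) -> str:
    # U+2212 (minus sign) shows up in typeset tables; map it to ASCII.
    return text.replace("−", "-")


def load_dataset(source: PathOrBuffer) -> pd.DataFrame:
    """Read a descriptor CSV into a validated dataset frame.

    Parameters
    ----------
    source : path or text buffer
        Comma-separated, UTF-8, ``.`` decimal.  The header must name
        ``name`` plus the seven numeric columns; ``subset`` is optional
        (missing or blank tags become ``unassigned``).

    Raises
    ------
    SchemaError
        if a required column is missing.
    ParseError
        if a cell is not numeric, naming the offending row and column.
    InvariantError
        if a row violates the type invariants (see module docstring).
    """
    raw = pd.read_csv(source, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]
    missing = [c for c in ("name",) + NUMERIC_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    out = pd.DataFrame()
    out["name"] = raw["name"].astype(str).str.strip()
    if "subset" in raw.columns:
        tags = raw["subset"].fillna("unassigned").astype(str).str.strip()
        tags = tags.replace("", "unassigned")
    else:
        tags = pd.Series("unassigned", index=raw.index)
    bad_tags = sorted(set(tags) - set(SUBSETS))
    if bad_tags:
        raise InvariantError(f"unknown subset tag(s): {', '.join(bad_tags)}")
    out["subset"] = tags

    for col in NUMERIC_COLUMNS:
        cells = raw[col].astype(str).map(_normalize_minus).str.strip()
        values = np.empty(len(cells))
        for i, cell in enumerate(cells):
            if cell in ("", "nan") and col == "mrtd":
                values[i] = np.nan
                continue
            try:
                values[i] = float(cell)
            except ValueError:
                raise ParseError(
                    f"row {i} ({out['name'].iloc[i]!r}), column {col!r}: "
                    f"cannot parse {cell!r} as a number"
                ) from None
        out[col] = values

    validate_dataset(out)
    return out


def validate_dataset(ds: pd.DataFrame) -> None:
    """Check the row invariants, raising :class:`InvariantError` on failure."""
    names = ds["name"]
    if (names == "").any():
        i = int(np.argmax((names == "").to_numpy()))
        raise InvariantError(f"row {i}: empty compound name")
    dupes = names[names.duplicated()].unique()
    if len(dupes):
        raise InvariantError(f"duplicate compound name(s): {', '.join(dupes)}")

    checks = [
        ("oxid_hl", ds["oxid_hl"] > 0, "oxid_hl must be > 0"),
        ("p_bd", (ds["p_bd"] >= 0) & (ds["p_bd"] <= 1), "p_bd must be in [0, 1]"),
        ("asol", ds["asol"] > 0, "asol must be > 0"),
        ("mw", ds["mw"] > 0, "mw must be > 0"),
        ("mrtd", ds["mrtd"].isna() | (ds["mrtd"] > 0), "mrtd must be > 0 when present"),
    ]
    for col in DESCRIPTOR_COLUMNS:
        checks.append((col, np.isfinite(ds[col].to_numpy()), f"{col} must be finite"))
    for col, ok, msg in checks:
        ok = np.asarray(ok, dtype=bool)
        if not ok.all():
            i = int(np.argmax(~ok))
            raise InvariantError(
                f"row {i} ({ds['name'].iloc[i]!r}): {msg} "
                f"(got {ds[col].iloc[i]!r})"
            )


def write_dataset(ds: pd.DataFrame, target: PathOrBuffer) -> None:
    """Write a dataset frame as CSV, preserving full float precision."""
    cols = ["name", "subset", *NUMERIC_COLUMNS]
    ds.loc[:, cols].to_csv(target, index=False)


def load_arv_mrtd() -> pd.DataFrame:
    """The bundled 31-compound antiretroviral MRTD dataset.

    The table holds the clinical MRTD (mg/kg/day) and six computed
    molecular property descriptors for 31 structurally diverse compounds,
    split into 23 training and 8 external test compounds as in the
    published study the models ship from.

    One value is corrected relative to the printed source table:
    Tipranavir's dose is stored as 16.70 mg/kg/day (consistent with its
    label dose of 500 mg twice daily for a 60 kg adult).  The printed
    value, 6.670, is a transcription error: every summary and model
    statistic published alongside the table (training mean/SD, regression
    R2/F/p-values, network training error) reproduces exactly only with
    16.70.
    """
    ref = resources.files("mrtdpred.data").joinpath("arv_mrtd.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return load_dataset(fh)


def subset_frame(ds: pd.DataFrame, subset: str | None) -> pd.DataFrame:
    """Rows tagged ``subset`` (stable order); all rows if ``subset`` is None."""
    if subset is None:
        return ds
    if subset not in SUBSETS:
        raise ValueError(f"unknown subset tag {subset!r}")
    out = ds[ds["subset"] == subset]
    if out.empty:
        raise ValueError(f"subset {subset!r} is empty")
    return out


def descriptor_matrix(X) -> np.ndarray:
    """Coerce descriptors to an ``(n, 6)`` float array in canonical order.

    Accepts a dataset frame (descriptor columns are selected by name), a
    mapping of column name to value, or an array-like already in canonical
    order.
    """
    if isinstance(X, pd.DataFrame):
        arr = X.loc[:, list(DESCRIPTOR_COLUMNS)].to_numpy(dtype=float)
    elif isinstance(X, (dict, pd.Series)):
        arr = np.array([[float(X[c]) for c in DESCRIPTOR_COLUMNS]])
    else:
        arr = np.atleast_2d(np.asarray(X, dtype=float))
    if arr.ndim != 2 or arr.shape[1] != len(DESCRIPTOR_COLUMNS):
        raise ValueError(
            f"expected (n, {len(DESCRIPTOR_COLUMNS)}) descriptor matrix, "
            f"got shape {arr.shape}"
        )
    return arr


def summarize(ds: pd.DataFrame, subset: str | None = None) -> pd.DataFrame:
    """Per-column n / mean / SD / CV% summary, as in the published table footer.

    SD uses the sample (n-1) divisor.  With a single row the SD is
    undefined and reported as NaN (not zero); CV% is undefined when the
    mean is zero.
    """
    sub = subset_frame(ds, subset)
    rows = {}
    for col in NUMERIC_COLUMNS:
        x = sub[col].dropna().to_numpy(dtype=float)
        n = len(x)
        if n == 0:
            raise ValueError(f"no values in column {col!r} for subset {subset!r}")
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1)) if n > 1 else np.nan
        cv = 100.0 * sd / mean if (mean != 0 and np.isfinite(sd)) else np.nan
        rows[col] = {"n": n, "mean": mean, "sd": sd, "cv_pct": cv}
    return pd.DataFrame(rows).T[["n", "mean", "sd", "cv_pct"]]
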