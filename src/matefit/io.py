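"""Reading and writing the plain-text tables and result documents.

Input tables are delimited text (comma or tab, autodetected) with a header
row.  A column map adapts arbitrary headers: pairs tables need a female and
a male trait column, singles tables a sex label and a trait column.  Results
are serialised as a single JSON document per run that round-trips
losslessly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .inference import FitResult, LRTResult, Z_95
from .model import TraitData

__all__ = [
    "read_pairs_table",
    "read_singles_table",
    "load_trait_data",
    "write_pairs_table",
    "write_singles_table",
    "ResultDocument",
    "build_result_document",
]

logger = logging.getLogger(__name__)

FEMALE_TOKENS = frozenset({"f", "female", "fem", "w", "0"})
MALE_TOKENS = frozenset({"m", "male", "1"})


def _read_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    return df


def _pick_column(df: pd.DataFrame, requested: str | None, fallbacks, what: str) -> str:
    if requested is not None:
        if requested not in df.columns:
            raise ValueError(
                f"column {requested!r} ({what}) not found; available: "
                f"{list(df.columns)}")
        return requested
    lower = {c.lower().strip(): c for c in df.columns}
    for cand in fallbacks:
        if cand in lower:
            return lower[cand]
    raise ValueError(
        f"could not locate the {what} column automatically; available "
        f"columns: {list(df.columns)}. Pass an explicit column map.")


def read_pairs_table(path, female_col: str | None = None,
                     male_col: str | None = None) -> np.ndarray:
    """Read a mated-pairs table; returns an (n, 2) array of (female, male).

    Rows with a missing value in either trait column are dropped with a
    logged count; non-numeric cells raise.
    """
    df = _read_table(path)
    fcol = _pick_column(df, female_col, ("female", "female_trait", "x"),
                        "female trait")
    mcol = _pick_column(df, male_col, ("male", "male_trait", "y"),
                        "male trait")
    sub = df[[fcol, mcol]].apply(pd.to_numeric, errors="coerce")
    bad_numeric = sub.isna() & df[[fcol, mcol]].notna()
    if bad_numeric.to_numpy().any():
        offenders = df.loc[bad_numeric.any(axis=1), [fcol, mcol]]
        raise ValueError(
            f"{path}: non-numeric trait values in rows "
            f"{list(offenders.index[:5])}")
    n_dropped = int(sub.isna().any(axis=1).sum())
    if n_dropped:
        logger.warning("%s: dropped %d row(s) with missing trait values",
                       path, n_dropped)
    sub = sub.dropna()
    if sub.empty:
        raise ValueError(f"{path}: no usable pair rows")
    return sub.to_numpy(dtype=float)


def read_singles_table(path, sex_col: str | None = None,
                       trait_col: str | None = None,
                       female_tokens=FEMALE_TOKENS,
                       male_tokens=MALE_TOKENS
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Read an unpaired-individuals table; returns (singles_x, singles_y).

    The sex column is matched case-insensitively after trimming whitespace;
    unknown sex tokens raise an error listing the offending values.
    """
    df = _read_table(path)
    scol = _pick_column(df, sex_col, ("sex", "gender"), "sex label")
    tcol = _pick_column(df, trait_col, ("trait", "value", "size", "length"),
                        "trait value")
    keep = df[[scol, tcol]].copy()
    keep[tcol] = pd.to_numeric(keep[tcol], errors="coerce")
    n_dropped = int(keep[tcol].isna().sum() + keep[scol].isna().sum())
    if n_dropped:
        logger.warning("%s: dropped %d row(s) with missing values", path,
                       n_dropped)
    keep = keep.dropna()
    sex = keep[scol].astype(str).str.strip().str.lower()
    is_f = sex.isin(female_tokens)
    is_m = sex.isin(male_tokens)
    unknown = sorted(set(sex[~(is_f | is_m)]))
    if unknown:
        raise ValueError(
            f"{path}: unrecognised sex labels {unknown}; expected one of "
            f"{sorted(female_tokens)} or {sorted(male_tokens)}")
    if keep.empty:
        raise ValueError(f"{path}: no usable single rows")
    return (keep.loc[is_f, tcol].to_numpy(dtype=float),
            keep.loc[is_m, tcol].to_numpy(dtype=float))


def load_trait_data(pairs_path, singles_path=None, units_label: str = "",
                    column_map: Mapping[str, str] | None = None) -> TraitData:
    """Assemble a TraitData from a pairs table and an optional singles table.

    ``column_map`` may contain keys ``female``, ``male``, ``sex``, ``trait``
    naming the corresponding table columns.
    """
    cmap = dict(column_map or {})
    pairs = read_pairs_table(pairs_path, cmap.get("female"), cmap.get("male"))
    if singles_path is not None:
        sx, sy = read_singles_table(singles_path, cmap.get("sex"),
                                    cmap.get("trait"))
    else:
        sx = sy = np.empty(0)
    return TraitData(pairs[:, 0], pairs[:, 1], sx, sy, units_label)


def write_pairs_table(data: TraitData, path) -> None:
    pd.DataFrame({"female": data.pairs_x,
                  "male": data.pairs_y}).to_csv(path, index=False)


def write_singles_table(data: TraitData, path) -> None:
    sex = ["F"] * data.n_singles_x + ["M"] * data.n_singles_y
    trait = np.concatenate([data.singles_x, data.singles_y])
    pd.DataFrame({"sex": sex, "trait": trait}).to_csv(path, index=False)


@dataclass
class ResultDocument:
    """Serialisable record of one fit run.

    Every confidence interval is stored as estimate plus explicit half-width
    so the document can be audited without recomputation.  Round-trips
    losslessly through JSON.
    """

    provenance: dict = field(default_factory=dict)
    estimates: dict = field(default_factory=dict)
    se: dict = field(default_factory=dict)
    ci_level: float = 0.95
    ci_halfwidths: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    loglik: float = float("nan")
    converged: bool = False
    message: str = ""
    rescale_factor: float = 1.0
    lrt: dict | None = None
    preference_interval: dict | None = None
    units_label: str = ""
    seed: int | None = None
    config: dict = field(default_factory=dict)
    version: str = __version__

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), indent=2, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "ResultDocument":
        return cls(**json.loads(text))

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "ResultDocument":
        with open(path) as fh:
            return cls.from_json(fh.read())


def build_result_document(fit: FitResult, level: float = 0.95,
                          lrt: LRTResult | None = None,
                          pref_interval=None,
                          provenance: Mapping | None = None,
                          units_label: str = "",
                          seed: int | None = None,
                          config: Mapping | None = None) -> ResultDocument:
    """Flatten a FitResult (plus optional LRT / preference interval) to a document."""
    from scipy.stats import norm as _norm
    z = Z_95 if level == 0.95 else float(_norm.ppf(0.5 + level / 2.0))
    doc = ResultDocument(
        provenance=dict(provenance or {}),
        estimates={n: fit.estimate(n) for n in
                   ("alpha", "delta", "mu_x", "mu_y", "sigma_x", "sigma_y")},
        se=dict(fit.se),
        ci_level=level,
        ci_halfwidths={n: z * s for n, s in fit.se.items()},
        fixed=dict(fit.fixed),
        loglik=fit.loglik,
        converged=fit.converged,
        message=fit.message,
        rescale_factor=fit.rescale_factor,
        units_label=units_label,
        seed=seed,
        config=dict(config or {}),
    )
    doc.provenance.setdefault("n_pairs", fit.n_pairs)
    doc.provenance.setdefault("n_singles_x", fit.n_singles_x)
    doc.provenance.setdefault("n_singles_y", fit.n_singles_y)
    if lrt is not None:
        doc.lrt = {"statistic": lrt.statistic, "df": lrt.df,
                   "p_value": lrt.p_value, "loglik_full": lrt.loglik_full,
                   "loglik_null": lrt.loglik_null}
    if pref_interval is not None:
        doc.preference_interval = {"p": pref_interval.p,
                                   "lower": pref_interval.lower,
                                   "upper": pref_interval.upper,
                                   "center": pref_interval.center}
    return doc
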