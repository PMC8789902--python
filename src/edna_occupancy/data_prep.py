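"""Survey-table IO, covariate pruning, and design-matrix construction.

A detection table records, for every water sample, how many of its K qPCR
replicates amplified.  Covariates live in a :class:`CovariateTable` that tags
each column continuous or categorical; the grouped design matrix encodes
continuous columns standardized, categoricals dummy-coded against a baseline
level, and interactions as products of standardized parents.  Each covariate
is one *group* for variable selection, so a categorical factor's dummy block
enters or leaves the model as a unit.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DETECTION_COLUMNS = ["site_id", "sample_id", "k_replicates", "y_positive"]


# ---------------------------------------------------------------------------
# detection table


def validate_detection_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a detection table (site_id, sample_id, k_replicates, y_positive).

    Raises ValueError naming the offending row for counts outside 0..K,
    non-integer counts, missing columns or duplicated (site, sample) keys.
    """
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"detection table missing columns: {missing}")
    df = df[DETECTION_COLUMNS].copy()
    for col in ("k_replicates", "y_positive"):
        vals = df[col]
        as_int = vals.astype(np.int64, errors="ignore")
        if not np.array_equal(np.asarray(vals, dtype=float), np.asarray(as_int, dtype=float)):
            bad = df.index[np.asarray(vals, dtype=float) != np.asarray(as_int, dtype=float)]
            raise ValueError(f"non-integer {col} at rows {list(bad[:5])}")
        df[col] = as_int
    if (df["k_replicates"] < 1).any():
        bad = df.index[df["k_replicates"] < 1]
        raise ValueError(f"k_replicates < 1 at rows {list(bad[:5])}")
    viol = (df["y_positive"] < 0) | (df["y_positive"] > df["k_replicates"])
    if viol.any():
        bad = df.index[viol]
        raise ValueError(
            f"y_positive outside 0..K at rows {list(bad[:5])} "
            f"(first offending row: {df.loc[bad[0]].to_dict()})"
        )
    dup = df.duplicated(subset=["site_id", "sample_id"])
    if dup.any():
        raise ValueError(f"duplicate (site_id, sample_id) at rows {list(df.index[dup][:5])}")
    return df


def read_detection_table(path) -> pd.DataFrame:
    """Read and validate a detection CSV."""
    return validate_detection_table(pd.read_csv(path))


def write_detection_table(df: pd.DataFrame, path) -> None:
    validate_detection_table(df).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# covariate table


@dataclass
class CovariateTable:
    """Site covariates with explicit typing.

    Attributes
    ----------
    data : DataFrame indexed however, containing `site_id` plus covariates.
    continuous : ordered list of continuous column names.
    categorical : mapping column name -> ordered list of levels.
    baseline : mapping column name -> baseline level (defaults to the first
        level in sorted order).
    """

    data: pd.DataFrame
    continuous: list[str]
    categorical: dict[str, list[str]] = field(default_factory=dict)
    baseline: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if "site_id" not in self.data.columns:
            raise ValueError("covariate table requires a site_id column")
        for name in self.continuous:
            if name not in self.data.columns:
                raise ValueError(f"continuous covariate {name!r} not in table")
        for name, levels in self.categorical.items():
            if name not in self.data.columns:
                raise ValueError(f"categorical covariate {name!r} not in table")
            observed = set(self.data[name].astype(str))
            unknown = observed - set(map(str, levels))
            if unknown:
                raise ValueError(f"{name!r} has levels outside its declared list: {unknown}")
            self.baseline.setdefault(name, sorted(map(str, levels))[0])
        if self.data[["site_id"] + self.continuous].isna().any().any():
            raise ValueError("missing values in covariate table")

    @classmethod
    def from_frame(cls, data: pd.DataFrame, categorical: dict[str, list[str]] | None = None,
                   baseline: dict[str, str] | None = None) -> "CovariateTable":
        """Infer typing: object/category columns are categorical, the rest continuous."""
        categorical = dict(categorical or {})
        cont = []
        for col in data.columns:
            if col == "site_id" or col in categorical:
                continue
            if data[col].dtype == object or isinstance(data[col].dtype, pd.CategoricalDtype):
                categorical[col] = sorted(data[col].astype(str).unique())
            else:
                cont.append(col)
        return cls(data=data, continuous=cont, categorical=categorical,
                   baseline=dict(baseline or {}))

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def prune_correlated(table: CovariateTable, threshold: float = 0.7,
                     priority: list[str] | None = None):
    """Drop one member of every continuous covariate pair with |r| >= threshold.

    Greedy by priority: covariates are visited in `priority` order (default:
    the table's column order) and kept only if not collinear with an
    already-kept covariate, so from each offending pair the lower-priority
    member is dropped.  Categorical covariates are never pruned.  Constant
    columns have undefined correlation; they are flagged, warned about, and
    treated as uncorrelated.

    Returns ``(retained_names, report)`` where `retained_names` covers all
    covariates (continuous survivors + every categorical) and `report` is a
    DataFrame of every evaluated pair with its Pearson r and drop decision.
    """
    cont = list(table.continuous)
    order = [c for c in (priority or cont) if c in cont]
    order += [c for c in cont if c not in order]
    X = table.data[cont].astype(float)
    sd = X.std(ddof=1)
    constant = [c for c in cont if not np.isfinite(sd[c]) or sd[c] == 0.0]
    if constant:
        warnings.warn(f"constant covariate(s) {constant}: correlation undefined, "
                      "treated as uncorrelated")
    corr = X.corr()
    kept: list[str] = []
    dropped: set[str] = set()
    rows = []
    for cand in order:
        drop = False
        for k in kept:
            r = corr.loc[cand, k]
            r_eff = 0.0 if (cand in constant or k in constant or not np.isfinite(r)) else r
            offending = abs(r_eff) >= threshold
            rows.append({"covariate_a": k, "covariate_b": cand, "pearson_r": r,
                         "dropped": cand if offending else ""})
            if offending:
                drop = True
        if drop:
            dropped.add(cand)
        else:
            kept.append(cand)
    # report also the pairs among kept that were never compared in visit order
    report = pd.DataFrame(rows, columns=["covariate_a", "covariate_b", "pearson_r", "dropped"])
    retained = [c for c in cont if c in kept] + list(table.categorical)
    return retained, report


# ---------------------------------------------------------------------------
# design matrix


@dataclass
class DesignMatrix:
    """Grouped regression design for the occupancy stage.

    X has an intercept column first; `groups` maps each term to its column
    span (the intercept is its own always-included group 'intercept').
    Standardization constants and baselines are stored so a fit can be
    reproduced and new sites encoded identically.
    """

    X: np.ndarray
    columns: list[str]
    groups: dict[str, list[int]]
    terms: list[str]
    standardization: dict[str, tuple[float, float]]
    baseline: dict[str, str]
    levels: dict[str, list[str]]
    site_ids: list

    @property
    def n_sites(self) -> int:
        return self.X.shape[0]

    @property
    def covariate_groups(self) -> list[str]:
        return [g for g in self.groups if g != "intercept"]

    def to_report(self) -> dict:
        return {
            "columns": self.columns,
            "groups": {k: list(map(int, v)) for k, v in self.groups.items()},
            "terms": self.terms,
            "standardization": {k: [float(m), float(s)] for k, (m, s) in
                                self.standardization.items()},
            "baseline": self.baseline,
            "levels": self.levels,
        }

    def write_report(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_report(), fh, indent=2)

    def decode_categorical(self, term: str) -> list[str]:
        """Recover each site's level of a categorical term from its dummy block."""
        if term not in self.levels:
            raise KeyError(f"{term!r} is not categorical")
        cols = self.groups[term]
        base = self.baseline[term]
        non_base = [l for l in self.levels[term] if l != base]
        block = self.X[:, cols]
        out = []
        for row in block:
            hits = np.flatnonzero(row == 1.0)
            out.append(base if hits.size == 0 else non_base[hits[0]])
        return out


def build_design_matrix(table: CovariateTable, formula: list[str],
                        standardization: dict[str, tuple[float, float]] | None = None,
                        levels: dict[str, list[str]] | None = None,
                        baseline: dict[str, str] | None = None,
                        ) -> DesignMatrix:
    """Build the grouped design matrix for the listed terms.

    `formula` entries are covariate names or interactions written ``"a:b"``
    (elementwise product of the two standardized parents, its own group).
    Passing `standardization` / `levels` / `baseline` from a previous fit
    encodes new data on the training scale; a categorical level unseen in
    training then raises.
    """
    df = table.data
    S = len(df)
    cols: list[np.ndarray] = [np.ones(S)]
    names = ["intercept"]
    groups: dict[str, list[int]] = {"intercept": [0]}
    stan: dict[str, tuple[float, float]] = {}
    fixed = standardization is not None

    def std_col(name: str) -> np.ndarray:
        raw = df[name].to_numpy(dtype=float)
        if fixed:
            if name not in standardization:
                raise KeyError(f"no stored standardization for {name!r}")
            m, s = standardization[name]
        else:
            m = raw.mean()
            s = raw.std(ddof=0)
            if s == 0.0:
                raise ValueError(f"covariate {name!r} is constant; cannot standardize")
        stan[name] = (m, s)
        return (raw - m) / s

    for term in formula:
        if ":" in term:
            a, b = term.split(":")
            for parent in (a, b):
                if parent not in table.continuous:
                    raise ValueError(f"interaction parent {parent!r} must be continuous")
            start = len(names)
            cols.append(std_col(a) * std_col(b))
            names.append(term)
            groups[term] = [start]
        elif term in table.continuous:
            start = len(names)
            cols.append(std_col(term))
            names.append(term)
            groups[term] = [start]
        elif term in table.categorical:
            term_levels = list(map(str, (levels or {}).get(term,
                                                           table.categorical[term])))
            base = str((baseline or {}).get(term, table.baseline[term]))
            observed = df[term].astype(str).to_numpy()
            unseen = set(observed) - set(term_levels)
            if unseen:
                raise ValueError(f"unseen level(s) {unseen} for categorical {term!r}")
            idx = []
            for lev in term_levels:
                if lev == base:
                    continue
                idx.append(len(names))
                cols.append((observed == lev).astype(float))
                names.append(f"{term}[{lev}]")
            groups[term] = idx
        else:
            raise ValueError(f"unknown covariate {term!r}")

    X = np.column_stack(cols)
    return DesignMatrix(
        X=X, columns=names, groups=groups, terms=list(formula),
        standardization=stan,
        baseline={t: str((baseline or {}).get(t, table.baseline[t]))
                  for t in formula if t in table.categorical},
        levels={t: list(map(str, (levels or {}).get(t, table.categorical[t])))
                for t in formula if t in table.categorical},
        site_ids=list(df["site_id"]),
    )


def destandardize(design: DesignMatrix, name: str) -> np.ndarray:
    """Map a standardized continuous column back to its raw scale."""
    m, s = design.standardization[name]
    col = design.groups[name]
    return design.X[:, col[0]] * s + m


# ---------------------------------------------------------------------------
# habitat suitability


def hsi_score(suitability_indices) -> float:
    """Habitat Suitability Index: geometric mean of the ten component indices.

    Each of the ten suitability indices scores one habitat feature for great
    crested newts on [0.01, 1]; the overall HSI is their geometric mean, so a
    single poor feature pulls the score down multiplicatively.
    """
    vals = np.asarray(suitability_indices, dtype=float)
    if vals.shape != (10,):
        raise ValueError("HSI requires exactly ten suitability indices")
    if (vals <= 0).any():
        raise ValueError("suitability indices must be positive")
    if (vals < 0.01).any() or (vals > 1).any():
        raise ValueError("suitability indices must lie in [0.01, 1]")
    return float(math.exp(np.log(vals).mean()))
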