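"""Synthetic eDNA surveys from the two-stage occupancy process.

The generator draws exactly the hierarchy the model assumes:

    z_i  ~ Bernoulli(psi_i)                      site occupancy
    w_ij ~ Bernoulli(theta11 if z_i else theta10)  sample contains DNA
    y_ij ~ Binomial(K, p11 if w_ij else p10)       amplifying qPCR replicates

Occupancy is either constant or covariate-driven, psi_i = logistic(x_i' beta),
with the design matrix built by the same `data_prep` code path used when
fitting — generator and model share one encoding.

Draw order under the single seeded generator is fixed and documented:
covariates (continuous columns left to right, then categorical columns),
then z, then w, then y.  Identical seeds give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_prep import CovariateTable, DesignMatrix, build_design_matrix


@dataclass
class CovariateSpec:
    """Recipe for a synthetic covariate table.

    n_continuous standard-normal columns (optionally correlated through a
    given correlation matrix) named x1..xn, plus categorical factors given as
    ``{name: n_levels}`` (level frequencies drawn once from Dirichlet(0.5,...)
    to emulate heavily unbalanced factors) or ``{name: [freq, ...]}``.
    """

    n_continuous: int = 0
    categorical: dict = field(default_factory=dict)
    correlation: np.ndarray | None = None


@dataclass
class GenParams:
    """Generating parameters of a simulated survey.

    occupancy_spec is either a constant psi in [0, 1] or a tuple
    ``(beta, covariate_spec)`` with beta aligned to the design columns
    (intercept first) produced from the covariate spec.
    """

    S: int
    M: int
    K: int
    theta11: float
    theta10: float
    p11: float
    p10: float
    occupancy_spec: float | tuple = 0.5
    seed: int = 0

    def __post_init__(self):
        for dim, v in (("S", self.S), ("M", self.M), ("K", self.K)):
            if int(v) < 1:
                raise ValueError(f"{dim} must be >= 1, got {v}")
        probs = {"theta11": self.theta11, "theta10": self.theta10,
                 "p11": self.p11, "p10": self.p10}
        if isinstance(self.occupancy_spec, (int, float)):
            probs["psi"] = float(self.occupancy_spec)
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class SimulatedSurvey:
    """A generated survey: observed detections plus the latent truth."""

    detection: pd.DataFrame        # site_id, sample_id, k_replicates, y_positive
    z: np.ndarray                  # (S,) latent site occupancy
    w: np.ndarray                  # (S, M) latent sample DNA state
    psi: np.ndarray                # (S,) occupancy probabilities used
    covariates: CovariateTable | None = None
    design: DesignMatrix | None = None

    def write(self, detection_path, covariates_path=None, truth_z_path=None,
              truth_w_path=None) -> None:
        self.detection.to_csv(detection_path, index=False)
        if covariates_path is not None and self.covariates is not None:
            self.covariates.write_csv(covariates_path)
        if truth_z_path is not None:
            pd.DataFrame({"site_id": self.detection["site_id"].unique(),
                          "z": self.z.astype(int)}).to_csv(truth_z_path, index=False)
        if truth_w_path is not None:
            S, M = self.w.shape
            pd.DataFrame({
                "site_id": np.repeat(self.detection["site_id"].unique(), M),
                "sample_id": np.tile([f"s{j+1}" for j in range(M)], S),
                "w": self.w.reshape(-1).astype(int),
            }).to_csv(truth_w_path, index=False)


def simulate_covariate_table(S: int, n_continuous: int, categorical_spec: dict | None,
                             seed_or_rng, correlation: np.ndarray | None = None,
                             ) -> CovariateTable:
    """Draw a synthetic site-covariate table.

    Continuous columns are standard normal (optionally with the requested
    correlation matrix, applied by Cholesky).  Categorical entries of
    `categorical_spec` are either an integer level count — frequencies then
    drawn from Dirichlet(0.5,...,0.5), emulating unbalanced factors — or an
    explicit frequency vector summing to 1.
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    data = {"site_id": [f"site{i+1:05d}" for i in range(S)]}
    cont_names = [f"x{i+1}" for i in range(n_continuous)]
    if n_continuous:
        Z = rng.standard_normal((S, n_continuous))
        if correlation is not None:
            C = np.asarray(correlation, dtype=float)
            if C.shape != (n_continuous, n_continuous):
                raise ValueError("correlation matrix shape mismatch")
            # allow singular (|r|=1) targets via eigen square root
            vals, vecs = np.linalg.eigh(C)
            if vals.min() < -1e-10:
                raise ValueError("correlation matrix not positive semidefinite")
            root = vecs @ np.diag(np.sqrt(np.clip(vals, 0, None))) @ vecs.T
            Z = Z @ root.T
        for j, name in enumerate(cont_names):
            data[name] = Z[:, j]
    categorical: dict[str, list[str]] = {}
    for name, spec in (categorical_spec or {}).items():
        if isinstance(spec, int):
            freqs = rng.dirichlet(np.full(spec, 0.5))
        else:
            freqs = np.asarray(spec, dtype=float)
            if abs(freqs.sum() - 1.0) > 1e-8 or (freqs < 0).any():
                raise ValueError(f"frequencies for {name!r} must be >= 0 and sum to 1")
        levels = [f"{name}_L{k+1:02d}" for k in range(len(freqs))]
        data[name] = rng.choice(levels, size=S, p=freqs)
        categorical[name] = levels
    return CovariateTable(data=pd.DataFrame(data), continuous=cont_names,
                          categorical=categorical)


def simulate_survey(params: GenParams) -> SimulatedSurvey:
    """Generate one survey from the two-stage occupancy process."""
    rng = np.random.default_rng(params.seed)
    S, M, K = params.S, params.M, params.K

    covariates = None
    design = None
    if isinstance(params.occupancy_spec, (int, float)):
        psi = np.full(S, float(params.occupancy_spec))
    else:
        beta, cov_spec = params.occupancy_spec
        covariates = simulate_covariate_table(
            S, cov_spec.n_continuous, cov_spec.categorical, rng,
            correlation=cov_spec.correlation)
        formula = ([f"x{i+1}" for i in range(cov_spec.n_continuous)]
                   + list(cov_spec.categorical))
        design = build_design_matrix(covariates, formula)
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (design.X.shape[1],):
            raise ValueError(
                f"beta has {beta.shape[0]} entries but the design has "
                f"{design.X.shape[1]} columns ({design.columns})")
        eta = design.X @ beta
        psi = 1.0 / (1.0 + np.exp(-eta))

    z = rng.random(S) < psi
    theta = np.where(z, params.theta11, params.theta10)
    w = rng.random((S, M)) < theta[:, None]
    p = np.where(w, params.p11, params.p10)
    y = rng.binomial(K, p)

    site_ids = (covariates.data["site_id"].to_numpy() if covariates is not None
                else np.array([f"site{i+1:05d}" for i in range(S)]))
    detection = pd.DataFrame({
        "site_id": np.repeat(site_ids, M),
        "sample_id": np.tile([f"s{j+1}" for j in range(M)], S),
        "k_replicates": K,
        "y_positive": y.reshape(-1),
    })
    return SimulatedSurvey(detection=detection, z=z.astype(int), w=w.astype(int),
                           psi=psi, covariates=covariates, design=design)
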