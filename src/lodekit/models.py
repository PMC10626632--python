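"""Linear energy models on invariant features, sklearn style.

The regression target is the total energy of a structure, modeled as a
sum of per-atom contributions,

    E = Σ_{species s} N_s ε_s + Σ_atoms w · x_i ,

with per-species baseline energies ε_s (unpenalized) and a ridge
penalty on the feature weights w. Forces enter the loss through the
analytic descriptor gradients: F_pred(j) = -Σ_i ∂x_i/∂r_j · w.

The reported accuracy metric is the %RMSE — the absolute RMSE divided
by the standard deviation σ of the training-set energies, ×100 — so a
mean predictor scores 100% on its own training set by construction.

``LodeFeatures`` / ``DensityFeatures`` are transformers turning lists
of structures into per-structure feature matrices (features are summed
over centers, grouped by the center's species); ``EnergyRidge`` is the
regressor. ``fit_linear`` and ``learning_curve`` are thin functional
wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin, clone

from .basis import BasisSpec
from .fields import InteractionSpec
from .invariants import radial_spectrum
from .lode import compute_lode
from .sr_density import compute_density_coefficients
from .structures import Structure

__all__ = [
    "LodeFeatures",
    "DensityFeatures",
    "EnergyRidge",
    "Metrics",
    "FitResult",
    "LearningCurveResult",
    "fit_linear",
    "learning_curve",
    "species_counts",
]

RIDGE_GRID = np.logspace(-12.0, 0.0, 13)


def species_counts(structures: list[Structure], species: list[str]) -> np.ndarray:
    """(n_structures, n_species) matrix of atom counts — baseline columns."""
    return np.array(
        [[sum(s == a for s in st.species) for a in species] for st in structures],
        dtype=float,
    )


def _union_species(structures: list[Structure]) -> list[str]:
    seen: dict[str, None] = {}
    for st in structures:
        for s in st.species_set():
            seen.setdefault(s)
    return sorted(seen)


class _BlockFeaturizer(BaseEstimator, TransformerMixin):
    """Shared plumbing: per-center radial-spectrum features summed per
    center species. Subclasses provide ``_block(structure)``."""

    def fit(self, X, y=None):
        self.species_ = _union_species(X)
        self.n_features_in_ = 1
        return self

    def _assemble(self, st: Structure, values: np.ndarray) -> np.ndarray:
        # values: (n_centers, n_flat); group-sum rows by center species
        out = np.zeros((len(self.species_), values.shape[1]))
        for i, s in enumerate(st.species):
            out[self.species_.index(s)] += values[i]
        return out.ravel()

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "species_"):
            raise RuntimeError("call fit before transform")
        rows = []
        for st in X:
            block = self._block(st)
            rows.append(self._assemble(st, radial_spectrum(block).values))
        return np.asarray(rows)

    def feature_names(self) -> list[str]:
        names = []
        for cs in self.species_:
            for a in self.species_:
                for n in range(self.n_max):
                    names.append(f"center={cs}|neighbor={a}|n={n}")
        return names


class LodeFeatures(_BlockFeaturizer):
    """Long-range descriptor features (l = 0 radial spectrum).

    One feature per (center species, neighbor species, n). With the
    default monomial basis and a small integration cutoff the single
    coefficient is essentially the potential at the atom.
    """

    def __init__(
        self,
        p: float = 1.0,
        smearing: float = 0.5,
        family: str = "monomial",
        n_max: int = 1,
        r_cut: float = 0.5,
        k_cutoff: float = 9.0,
        include_center: bool = True,
    ):
        self.p = p
        self.smearing = smearing
        self.family = family
        self.n_max = n_max
        self.r_cut = r_cut
        self.k_cutoff = k_cutoff
        self.include_center = include_center

    def _spec_basis(self):
        return (
            InteractionSpec(p=self.p, smearing=self.smearing),
            BasisSpec(self.family, self.n_max, 0, self.r_cut),
        )

    def _block(self, st: Structure):
        spec, basis = self._spec_basis()
        return compute_lode(
            st, spec, basis, self.k_cutoff,
            include_center=self.include_center, species_channels=self.species_,
        )

    def transform_with_gradients(self, X):
        """Features plus per-structure gradient arrays (n_atoms, 3, n_feat)."""
        spec, basis = self._spec_basis()
        feats, grads = [], []
        for st in X:
            block = compute_lode(
                st, spec, basis, self.k_cutoff, with_gradients=True,
                include_center=self.include_center, species_channels=self.species_,
            )
            vals = block.values[..., 0].reshape(len(st), -1)
            feats.append(self._assemble(st, vals))
            g = block.gradients[..., 0].reshape(len(st), len(st), 3, -1)
            gfull = np.zeros((len(st), 3, len(self.species_), g.shape[-1]))
            for i, s in enumerate(st.species):
                gfull[:, :, self.species_.index(s), :] += g[i]
            grads.append(gfull.reshape(len(st), 3, -1))
        return np.asarray(feats), grads


class DensityFeatures(_BlockFeaturizer):
    """Short-range smeared-density features (l = 0 radial spectrum)."""

    def __init__(
        self,
        smearing: float = 0.5,
        family: str = "gto",
        n_max: int = 8,
        r_cut: float = 9.0,
        taper: bool = False,
    ):
        self.smearing = smearing
        self.family = family
        self.n_max = n_max
        self.r_cut = r_cut
        self.taper = taper

    def _block(self, st: Structure):
        basis = BasisSpec(self.family, self.n_max, 0, self.r_cut)
        return compute_density_coefficients(
            st, self.smearing, basis,
            species_channels=self.species_, taper=self.taper,
        )


# ---------------------------------------------------------------------------
# ridge model
# ---------------------------------------------------------------------------


@dataclass
class Metrics:
    rmse: float
    sigma_train: float
    percent_rmse: float


def _metrics(rmse: float, sigma: float) -> Metrics:
    if sigma == 0.0:
        pct = 0.0 if rmse < 1e-10 else float("inf")
    else:
        pct = 100.0 * rmse / sigma
    return Metrics(float(rmse), float(sigma), float(pct))


class EnergyRidge(BaseEstimator, RegressorMixin):
    """Ridge regression of total energies with per-species baselines.

    ``ridge="auto"`` selects the penalty from a 10^-12..1 grid on an
    inner 80/20 validation split of the training data (seeded); pass a
    float to fix it. ``force_weight`` > 0 adds force residual rows when
    forces and feature gradients are supplied to :meth:`fit`.
    """

    def __init__(
        self,
        ridge: float | str = "auto",
        force_weight: float = 0.0,
        standardize: bool = True,
        seed: int = 0,
    ):
        self.ridge = ridge
        self.force_weight = force_weight
        self.standardize = standardize
        self.seed = seed

    # -- internals ------------------------------------------------------
    def _solve(self, xs, counts, y, lam, grad_rows=None, f_targets=None):
        nf, nb = xs.shape[1], counts.shape[1]
        a_top = np.hstack([xs, counts])
        lhs = a_top.T @ a_top
        rhs = a_top.T @ y
        if grad_rows is not None:
            lhs[:nf, :nf] += grad_rows.T @ grad_rows
            rhs[:nf] += grad_rows.T @ f_targets
        lhs[:nf, :nf] += lam * np.eye(nf)
        if lam <= 0.0:
            try:
                sol = np.linalg.solve(lhs, rhs)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    "normal equations singular; increase the ridge parameter"
                ) from exc
        else:
            # the unpenalized baseline columns may be collinear (e.g. fixed
            # stoichiometry): take the minimum-norm solution
            sol = np.linalg.lstsq(lhs, rhs, rcond=None)[0]
        return sol[:nf], sol[nf:]

    def _prepare(self, X, counts):
        x = np.asarray(X, dtype=float)
        if counts is None:
            counts = np.ones((x.shape[0], 1))
        return x, np.asarray(counts, dtype=float)

    def fit(self, X, y, counts=None, forces=None, gradients=None):
        """X: (n, f) per-structure features; counts: (n, n_species);
        forces: list of (n_atoms, 3); gradients: list of (n_atoms, 3, f)."""
        x, counts = self._prepare(X, counts)
        y = np.asarray(y, dtype=float)
        self.scale_ = (
            np.where(x.std(axis=0) > 1e-14, x.std(axis=0), 1.0)
            if self.standardize
            else np.ones(x.shape[1])
        )
        xs = x / self.scale_
        grad_rows = f_targets = None
        if forces is not None and self.force_weight > 0:
            if gradients is None:
                raise ValueError("force training needs feature gradients")
            sw = np.sqrt(self.force_weight)
            grad_rows = np.vstack(
                [-sw * g.reshape(-1, g.shape[-1]) / self.scale_ for g in gradients]
            )
            f_targets = np.concatenate([sw * f.ravel() for f in forces])

        if isinstance(self.ridge, str):
            self.ridge_ = self._auto_ridge(xs, counts, y, grad_rows, f_targets)
        else:
            self.ridge_ = float(self.ridge)
        w, b = self._solve(xs, counts, y, self.ridge_, grad_rows, f_targets)
        self.weights_ = w / self.scale_
        self.baseline_ = b
        resid = x @ self.weights_ + counts @ b - y
        self.metrics_ = _metrics(
            np.sqrt(np.mean(resid**2)), float(np.std(y, ddof=0))
        )
        return self

    def _auto_ridge(self, xs, counts, y, grad_rows, f_targets):
        n = xs.shape[0]
        if n < 10:
            return 1e-8
        rng = np.random.default_rng(self.seed)
        idx = rng.permutation(n)
        n_val = max(2, n // 5)
        val, tr = idx[:n_val], idx[n_val:]
        best, best_err = RIDGE_GRID[0], np.inf
        for lam in RIDGE_GRID:
            try:
                w, b = self._solve(xs[tr], counts[tr], y[tr], lam)
            except np.linalg.LinAlgError:
                continue
            err = np.sqrt(np.mean((xs[val] @ w + counts[val] @ b - y[val]) ** 2))
            if err < best_err:
                best, best_err = lam, err
        return float(best)

    def predict(self, X, counts=None):
        x, counts = self._prepare(X, counts)
        return x @ self.weights_ + counts @ self.baseline_

    def predict_forces(self, gradients):
        """F(j) = -Σ_f ∂x_f/∂r_j · w_f per structure."""
        return [-g @ self.weights_ for g in gradients]


@dataclass
class FitResult:
    weights: np.ndarray
    ridge: float
    baseline: np.ndarray
    metrics: Metrics
    model: EnergyRidge


def fit_linear(
    features,
    energies,
    counts=None,
    forces=None,
    gradients=None,
    ridge: float | str = "auto",
    force_weight: float = 0.0,
    seed: int = 0,
) -> FitResult:
    """Fit a ridge model; deterministic given inputs and seed."""
    est = EnergyRidge(
        ridge=ridge, force_weight=force_weight, seed=seed
    ).fit(features, energies, counts=counts, forces=forces, gradients=gradients)
    return FitResult(est.weights_, est.ridge_, est.baseline_, est.metrics_, est)


# ---------------------------------------------------------------------------
# learning curves
# ---------------------------------------------------------------------------


@dataclass
class LearningCurveResult:
    """Validation %RMSE against training-set size.

    ``table`` has one row per (train_size, repeat); ``summary()``
    aggregates mean/std per size.
    """

    table: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        return (
            self.table.groupby("train_size")["percent_rmse"]
            .agg(["mean", "std"])
            .reset_index()
        )

    def at(self, size: int) -> float:
        rows = self.table[self.table.train_size == size]
        return float(rows.percent_rmse.mean())


def learning_curve(
    estimator: EnergyRidge,
    X,
    y,
    counts=None,
    train_sizes=(10, 30, 100, 300, 800),
    n_repeats: int = 1,
    seed: int = 0,
    val_fraction: float = 0.2,
) -> LearningCurveResult:
    """Learning curve with a fixed held-out validation split.

    The 80/20 train-pool/validation split is made once by a seeded
    shuffle and kept fixed across sizes; repeats resample the training
    subset only. %RMSE is the validation RMSE over the standard
    deviation of the sampled training energies.
    """
    x = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    counts = np.ones((x.shape[0], 1)) if counts is None else np.asarray(counts, float)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(x.shape[0])
    n_val = int(round(val_fraction * x.shape[0]))
    val, pool = idx[:n_val], idx[n_val:]
    rows = []
    for size in train_sizes:
        if size > pool.size:
            raise ValueError(f"train size {size} exceeds pool of {pool.size}")
        for rep in range(n_repeats):
            sub = rng.permutation(pool)[:size] if rep else pool[:size]
            est = clone(estimator)
            est.fit(x[sub], y[sub], counts=counts[sub])
            pred = est.predict(x[val], counts=counts[val])
            rmse = float(np.sqrt(np.mean((pred - y[val]) ** 2)))
            m = _metrics(rmse, float(np.std(y[sub], ddof=0)))
            rows.append(
                {
                    "train_size": size,
                    "repeat": rep,
                    "rmse": m.rmse,
                    "percent_rmse": m.percent_rmse,
                }
            )
    return LearningCurveResult(pd.DataFrame(rows))
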