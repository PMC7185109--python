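"""Model / Results facade over the Split LBI machinery.

`SplitLBIModel` holds the data and hyperparameters; `fit()` runs the
regularization path and returns a `SplitLBIResults` carrying the dense
and sparse estimates, the path, diagnostics, and a text `summary()` —
the same shape statsmodels users expect from a fitted model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .crossval import binary_metrics, roc_auc
from .grid import VoxelMask
from .lbi import (
    LBIPath,
    ModelHyperparams,
    ModelState,
    Standardizer,
    fit_path,
    logistic_loss,
    predict_label,
    predict_proba,
    select_checkpoint,
    sparse_projection,
)
from .operator import DifferenceOperator, build_difference_operator
from .simulate import CohortDataset

__all__ = ["SplitLBIModel", "SplitLBIResults"]


class SplitLBIModel:
    """Sparse structured logistic classifier for masked voxel features.

    Parameters
    ----------
    endog : (n,) binary labels (1 = case).
    exog : (n, P) feature matrix, one column per in-mask voxel.
    mask : VoxelMask or None.  When given, the structured penalty
        couples 6-neighbour voxel pairs; when None the penalty reduces
        to pure voxel-level sparsity (identity operator).
    """

    def __init__(
        self,
        endog,
        exog,
        mask: VoxelMask | None = None,
        nu: float = 1.0,
        kappa: float = 10.0,
        rho: float = 1.0,
        standardize: bool = True,
        **hyper_kw,
    ):
        self.endog = np.asarray(endog)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog/exog shape mismatch")
        self.mask = mask
        self.hyper = ModelHyperparams(nu=nu, kappa=kappa, rho=rho, **hyper_kw)
        self.standardize = standardize
        if mask is not None:
            if mask.n_features != self.exog.shape[1]:
                raise ValueError("mask feature count does not match exog")
            self.operator: DifferenceOperator = build_difference_operator(mask, rho)
        else:
            from scipy import sparse

            P = self.exog.shape[1]
            self.operator = DifferenceOperator(
                sparse.identity(P, format="csr"), P, 0, 0.0,
                np.empty((0, 2), dtype=np.int64),
            )

    @classmethod
    def from_cohort(cls, dataset: CohortDataset, **kw) -> "SplitLBIModel":
        return cls(dataset.labels, dataset.features, mask=dataset.mask, **kw)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_col: str, feature_cols=None, **kw
    ) -> "SplitLBIModel":
        if feature_cols is None:
            feature_cols = [c for c in df.columns if c != label_col]
        return cls(df[label_col].to_numpy(), df[feature_cols].to_numpy(), **kw)

    def fit(
        self,
        t_max: float | None = None,
        val_fraction: float = 0.2,
        seed: int | None = None,
    ) -> "SplitLBIResults":
        """Run the path and select a checkpoint.

        With t_max unset, an internal stratified ``val_fraction`` split
        drives the stopping rule and checkpoint selection; with t_max
        given and val_fraction = 0 the final checkpoint is returned.
        """
        seed = self.hyper.seed if seed is None else seed
        hyper = self.hyper
        if t_max is not None:
            from dataclasses import replace

            hyper = replace(hyper, t_max=t_max)
        std = Standardizer.fit(self.exog) if self.standardize else None
        Xs = std.transform(self.exog) if std else self.exog
        y = self.endog
        if val_fraction > 0:
            idx_tr, idx_val = train_test_split(
                np.arange(len(y)),
                test_size=val_fraction,
                stratify=y,
                random_state=seed % (2**32),
            )
            path = fit_path(
                Xs[idx_tr], y[idx_tr], self.operator, hyper, Xs[idx_val], y[idx_val]
            )
            selected = select_checkpoint(path, Xs[idx_val], y[idx_val], use_cached=True)
        else:
            if hyper.t_max is None:
                raise ValueError("set t_max or a positive val_fraction")
            path = fit_path(Xs, y, self.operator, hyper, None, None)
            selected = path.checkpoints[-1]
        return SplitLBIResults(self, path, selected, std)


class SplitLBIResults:
    """Results of a Split LBI fit: dense params, sparse params, path."""

    def __init__(
        self,
        model: SplitLBIModel,
        path: LBIPath,
        selected: ModelState,
        standardizer: Standardizer | None,
    ):
        self.model = model
        self.path = path
        self.selected = selected
        self.standardizer = standardizer
        est = sparse_projection(selected, model.operator)
        self.sparse_params = est.beta_tilde
        self.support = est.support

    @property
    def params(self) -> np.ndarray:
        """Dense coefficients beta (standardized-feature scale)."""
        return self.selected.beta

    @property
    def intercept(self) -> float:
        return self.selected.intercept

    def _transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.standardizer.transform(X) if self.standardizer else X

    def predict_proba(self, X=None) -> np.ndarray:
        X = self.model.exog if X is None else X
        return predict_proba(self.selected, self._transform(X))

    def predict(self, X=None) -> np.ndarray:
        X = self.model.exog if X is None else X
        return predict_label(self.selected, self._transform(X))

    def deviance(self, X=None, y=None) -> float:
        X = self.model.exog if X is None else X
        y = self.model.endog if y is None else y
        return logistic_loss(self.selected.beta, self.selected.intercept, self._transform(X), y)

    def summary(self) -> str:
        m = self.model
        y = m.endog
        pred = self.predict()
        acc, sens, spec = binary_metrics(y, pred)
        auc = roc_auc(y, self.predict_proba()) if len(np.unique(y)) == 2 else float("nan")
        h = m.hyper
        lines = [
            "Split LBI classification results",
            "=" * 44,
            f"{'No. subjects:':<28}{len(y)}",
            f"{'No. voxels (P):':<28}{m.exog.shape[1]}",
            f"{'No. neighbour edges (E):':<28}{m.operator.n_edges}",
            f"{'nu / kappa / rho:':<28}{h.nu:g} / {h.kappa:g} / {h.rho:g}",
            f"{'step size alpha:':<28}{self.path.alpha:.3e}",
            f"{'selected t:':<28}{self.selected.t:.4f} (step {self.selected.k})",
            f"{'support size |supp(gamma)|:':<28}{len(self.support)}",
            f"{'train deviance:':<28}{self.deviance():.3f}",
            f"{'train accuracy:':<28}{acc:.4f}",
            f"{'train sensitivity:':<28}{sens:.4f}",
            f"{'train specificity:':<28}{spec:.4f}",
            f"{'train AUC:':<28}{auc:.4f}",
            "=" * 44,
        ]
        return "\n".join(lines)
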