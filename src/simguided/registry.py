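"""The single-algorithm configuration registry.

A versioned, frozen inventory of learner configurations: 21 classification
configurations drawn from 8 algorithm families and 32 regression
configurations from 9 families.  Each configuration is either a
``defaults`` entry (fixed hyperparameters) or a ``bayes_opt`` entry whose
bounded search space is tuned in the inner cross-validation loop.  The
family list follows the published inventory: classification uses logistic
regression, naive Bayes, random forest, decision trees, tree ensembles,
SVMs with several kernels, k-nearest neighbour, and a linear classifier
for high-dimensional data; regression adds Gaussian processes, generalized
linear models, ensemble regressors, and L1-regularized linear/SVM models.
The exact per-configuration hyperparameter inventories are this package's
own reconstruction (documented in docs/methods.md); counts and family
coverage are the frozen contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

from sklearn.dummy import DummyClassifier, DummyRegressor
from sklearn.ensemble import (
    AdaBoostRegressor,
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, Matern, WhiteKernel
from sklearn.linear_model import (
    Lasso,
    LinearRegression,
    LogisticRegression,
    Ridge,
    SGDClassifier,
    SGDRegressor,
    TweedieRegressor,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .optimize import Dimension, SearchSpace

__all__ = [
    "AlgorithmConfig",
    "classification_registry",
    "regression_registry",
    "baseline_config",
    "get_config",
    "REGISTRY_VERSION",
]

REGISTRY_VERSION = "1.0"

Task = Literal["classification", "regression"]


@dataclass(frozen=True)
class AlgorithmConfig:
    """One registry entry: family, mode, and (for bayes_opt) a search space."""

    id: str
    task: Task
    family: str
    mode: Literal["defaults", "bayes_opt"]
    builder: Callable[..., object] = field(compare=False, repr=False)
    space: SearchSpace | None = None

    def __post_init__(self) -> None:
        if self.mode == "bayes_opt" and self.space is None:
            raise ValueError(f"bayes_opt config {self.id!r} needs a search space")

    def default_params(self) -> dict:
        return self.space.default_point() if self.space is not None else {}

    def build(self, params: dict | None = None, seed: int = 0):
        """Instantiate the underlying estimator at the given hyperparameters."""
        return self.builder(**(params or self.default_params()), seed=seed)


def _dim(name, low=None, high=None, **kw) -> Dimension:
    return Dimension(name, low=low, high=high, **kw)


# ---------------------------------------------------------------------------
# classification: 8 families, 21 configurations

def _logreg(C: float = 1.0, seed: int = 0):
    return LogisticRegression(C=C, max_iter=2000)


def _gnb(var_smoothing: float = 1e-9, seed: int = 0):
    return GaussianNB(var_smoothing=var_smoothing)


def _rfc(n_estimators: int = 100, max_depth=None, min_samples_leaf: int = 1,
         seed: int = 0):
    return RandomForestClassifier(
        n_estimators=n_estimators, max_depth=max_depth,
        min_samples_leaf=min_samples_leaf, random_state=seed)


def _dtc(max_depth=None, min_samples_leaf: int = 1, seed: int = 0):
    return DecisionTreeClassifier(max_depth=max_depth,
                                  min_samples_leaf=min_samples_leaf,
                                  random_state=seed)


def _gbc(n_estimators: int = 100, learning_rate: float = 0.1,
         max_depth: int = 3, seed: int = 0):
    return GradientBoostingClassifier(
        n_estimators=n_estimators, learning_rate=learning_rate,
        max_depth=max_depth, random_state=seed)


def _svc(kernel: str):
    def build(C: float = 1.0, gamma: float | str = "scale", degree: int = 3,
              seed: int = 0):
        return SVC(kernel=kernel, C=C, gamma=gamma, degree=degree,
                   random_state=seed)
    return build


def _knn(n_neighbors: int = 5, seed: int = 0):
    return KNeighborsClassifier(n_neighbors=n_neighbors)


def _sgdc(penalty: str = "l2", alpha: float = 1e-4, seed: int = 0):
    return SGDClassifier(loss="log_loss", penalty=penalty, alpha=alpha,
                         max_iter=2000, tol=1e-4, random_state=seed)


def classification_registry() -> list[AlgorithmConfig]:
    """The frozen 21-configuration classification inventory (8 families)."""
    C = "classification"
    c_C = _dim("C", 1e-3, 1e3, log=True)
    cfgs = [
        AlgorithmConfig("logreg_default", C, "logistic_regression", "defaults",
                        _logreg),
        AlgorithmConfig("logreg_bo", C, "logistic_regression", "bayes_opt",
                        _logreg, SearchSpace((c_C,), {"C": 1.0})),
        AlgorithmConfig("naive_bayes_default", C, "naive_bayes", "defaults",
                        _gnb),
        AlgorithmConfig("naive_bayes_bo", C, "naive_bayes", "bayes_opt", _gnb,
                        SearchSpace((_dim("var_smoothing", 1e-12, 1e-3,
                                          log=True),),
                                    {"var_smoothing": 1e-9})),
        AlgorithmConfig("rf_default", C, "random_forest", "defaults", _rfc),
        AlgorithmConfig("rf_bo", C, "random_forest", "bayes_opt", _rfc,
                        SearchSpace((_dim("n_estimators", 20, 200, integer=True),
                                     _dim("max_depth", 2, 12, integer=True),
                                     _dim("min_samples_leaf", 1, 10,
                                          integer=True)),
                                    {"n_estimators": 100, "max_depth": 8,
                                     "min_samples_leaf": 1})),
        AlgorithmConfig("dtree_default", C, "decision_tree", "defaults", _dtc),
        AlgorithmConfig("dtree_bo", C, "decision_tree", "bayes_opt", _dtc,
                        SearchSpace((_dim("max_depth", 1, 15, integer=True),
                                     _dim("min_samples_leaf", 1, 20,
                                          integer=True)),
                                    {"max_depth": 8, "min_samples_leaf": 1})),
        AlgorithmConfig("tree_ensemble_default", C, "tree_ensemble", "defaults",
                        _gbc),
        AlgorithmConfig("tree_ensemble_bo", C, "tree_ensemble", "bayes_opt",
                        _gbc,
                        SearchSpace((_dim("n_estimators", 20, 200, integer=True),
                                     _dim("learning_rate", 0.01, 1.0, log=True),
                                     _dim("max_depth", 1, 5, integer=True)),
                                    {"n_estimators": 100, "learning_rate": 0.1,
                                     "max_depth": 3})),
        AlgorithmConfig("svm_linear_default", C, "svm", "defaults",
                        _svc("linear")),
        AlgorithmConfig("svm_linear_bo", C, "svm", "bayes_opt", _svc("linear"),
                        SearchSpace((c_C,), {"C": 1.0})),
        AlgorithmConfig("svm_poly_default", C, "svm", "defaults", _svc("poly")),
        AlgorithmConfig("svm_poly_bo", C, "svm", "bayes_opt", _svc("poly"),
                        SearchSpace((c_C, _dim("degree", 2, 4, integer=True)),
                                    {"C": 1.0, "degree": 3})),
        AlgorithmConfig("svm_rbf_default", C, "svm", "defaults", _svc("rbf")),
        AlgorithmConfig("svm_rbf_bo", C, "svm", "bayes_opt", _svc("rbf"),
                        SearchSpace((c_C, _dim("gamma", 1e-4, 10.0, log=True)),
                                    {"C": 1.0, "gamma": 0.1})),
        AlgorithmConfig("knn_default", C, "knn", "defaults", _knn),
        AlgorithmConfig("knn_bo", C, "knn", "bayes_opt", _knn,
                        SearchSpace((_dim("n_neighbors", 1, 30, integer=True),),
                                    {"n_neighbors": 5})),
        AlgorithmConfig("linear_highdim_l2", C, "linear_highdim", "defaults",
                        _sgdc),
        AlgorithmConfig("linear_highdim_l1", C, "linear_highdim", "defaults",
                        lambda seed=0: _sgdc(penalty="l1", seed=seed)),
        AlgorithmConfig("linear_highdim_bo", C, "linear_highdim", "bayes_opt",
                        _sgdc,
                        SearchSpace((_dim("alpha", 1e-6, 1.0, log=True),
                                     _dim("penalty",
                                          choices=("l2", "l1", "elasticnet"))),
                                    {"alpha": 1e-4, "penalty": "l2"})),
    ]
    return cfgs


# ---------------------------------------------------------------------------
# regression: 9 families, 32 configurations

def _ridge(alpha: float = 1.0, seed: int = 0):
    return Ridge(alpha=alpha, random_state=seed)


def _svr(kernel: str):
    def build(C: float = 1.0, gamma: float | str = "scale", degree: int = 3,
              epsilon: float = 0.1, seed: int = 0):
        return SVR(kernel=kernel, C=C, gamma=gamma, degree=degree,
                   epsilon=epsilon)
    return build


def _gpr(kernel_name: str = "rbf"):
    def build(alpha: float = 1e-2, seed: int = 0):
        base = RBF(1.0) if kernel_name == "rbf" else Matern(1.0, nu=1.5)
        return GaussianProcessRegressor(
            kernel=1.0 * base + WhiteKernel(1e-1), alpha=alpha,
            normalize_y=True, random_state=seed)
    return build


def _dtr(max_depth=None, min_samples_leaf: int = 1, seed: int = 0):
    return DecisionTreeRegressor(max_depth=max_depth,
                                 min_samples_leaf=min_samples_leaf,
                                 random_state=seed)


def _glm(alpha: float = 1.0, seed: int = 0):
    return TweedieRegressor(power=0, alpha=alpha, max_iter=1000)


def _gbr(n_estimators: int = 100, learning_rate: float = 0.1,
         max_depth: int = 3, seed: int = 0):
    return GradientBoostingRegressor(
        n_estimators=n_estimators, learning_rate=learning_rate,
        max_depth=max_depth, random_state=seed)


def _ada(n_estimators: int = 50, learning_rate: float = 1.0, seed: int = 0):
    return AdaBoostRegressor(n_estimators=n_estimators,
                             learning_rate=learning_rate, random_state=seed)


def _rfr(n_estimators: int = 100, max_depth=None, min_samples_leaf: int = 1,
         seed: int = 0):
    return RandomForestRegressor(
        n_estimators=n_estimators, max_depth=max_depth,
        min_samples_leaf=min_samples_leaf, random_state=seed)


def _lasso(alpha: float = 1.0, seed: int = 0):
    return Lasso(alpha=alpha, max_iter=5000, random_state=seed)


def _l1svr(loss: str = "epsilon_insensitive"):
    def build(alpha: float = 1e-4, epsilon: float = 0.1, seed: int = 0):
        return SGDRegressor(loss=loss, penalty="l1", alpha=alpha,
                            epsilon=epsilon, max_iter=2000, tol=1e-4,
                            random_state=seed)
    return build


def regression_registry() -> list[AlgorithmConfig]:
    """The frozen 32-configuration regression inventory (9 families)."""
    R = "regression"
    r_C = _dim("C", 1e-3, 1e3, log=True)
    alpha_log = _dim("alpha", 1e-4, 1e2, log=True)
    cfgs = [
        AlgorithmConfig("linreg_ols", R, "linear_regression", "defaults",
                        lambda seed=0: LinearRegression()),
        AlgorithmConfig("linreg_ridge_default", R, "linear_regression",
                        "defaults", _ridge),
        AlgorithmConfig("linreg_ridge_bo", R, "linear_regression", "bayes_opt",
                        _ridge, SearchSpace((alpha_log,), {"alpha": 1.0})),
        AlgorithmConfig("svr_linear_default", R, "svm", "defaults",
                        _svr("linear")),
        AlgorithmConfig("svr_linear_bo", R, "svm", "bayes_opt", _svr("linear"),
                        SearchSpace((r_C,), {"C": 1.0})),
        AlgorithmConfig("svr_poly_default", R, "svm", "defaults", _svr("poly")),
        AlgorithmConfig("svr_poly_bo", R, "svm", "bayes_opt", _svr("poly"),
                        SearchSpace((r_C, _dim("degree", 2, 4, integer=True)),
                                    {"C": 1.0, "degree": 3})),
        AlgorithmConfig("svr_rbf_default", R, "svm", "defaults", _svr("rbf")),
        AlgorithmConfig("svr_rbf_bo", R, "svm", "bayes_opt", _svr("rbf"),
                        SearchSpace((r_C, _dim("gamma", 1e-4, 10.0, log=True)),
                                    {"C": 1.0, "gamma": 0.1})),
        AlgorithmConfig("gp_rbf_default", R, "gaussian_process", "defaults",
                        _gpr("rbf")),
        AlgorithmConfig("gp_rbf_bo", R, "gaussian_process", "bayes_opt",
                        _gpr("rbf"),
                        SearchSpace((_dim("alpha", 1e-6, 1.0, log=True),),
                                    {"alpha": 1e-2})),
        AlgorithmConfig("gp_matern_default", R, "gaussian_process", "defaults",
                        _gpr("matern")),
        AlgorithmConfig("rtree_default", R, "regression_tree", "defaults",
                        _dtr),
        AlgorithmConfig("rtree_bo", R, "regression_tree", "bayes_opt", _dtr,
                        SearchSpace((_dim("max_depth", 1, 15, integer=True),
                                     _dim("min_samples_leaf", 1, 20,
                                          integer=True)),
                                    {"max_depth": 8, "min_samples_leaf": 1})),
        AlgorithmConfig("rtree_shallow", R, "regression_tree", "defaults",
                        lambda seed=0: _dtr(max_depth=3, seed=seed)),
        AlgorithmConfig("glm_unpenalized", R, "glm", "defaults",
                        lambda seed=0: _glm(alpha=0.0, seed=seed)),
        AlgorithmConfig("glm_default", R, "glm", "defaults", _glm),
        AlgorithmConfig("glm_bo", R, "glm", "bayes_opt", _glm,
                        SearchSpace((alpha_log,), {"alpha": 1.0})),
        AlgorithmConfig("ens_gb_default", R, "ensemble_regression", "defaults",
                        _gbr),
        AlgorithmConfig("ens_gb_bo", R, "ensemble_regression", "bayes_opt",
                        _gbr,
                        SearchSpace((_dim("n_estimators", 20, 200, integer=True),
                                     _dim("learning_rate", 0.01, 1.0, log=True),
                                     _dim("max_depth", 1, 5, integer=True)),
                                    {"n_estimators": 100, "learning_rate": 0.1,
                                     "max_depth": 3})),
        AlgorithmConfig("ens_ada_default", R, "ensemble_regression", "defaults",
                        _ada),
        AlgorithmConfig("ens_ada_bo", R, "ensemble_regression", "bayes_opt",
                        _ada,
                        SearchSpace((_dim("n_estimators", 10, 200, integer=True),
                                     _dim("learning_rate", 0.01, 2.0, log=True)),
                                    {"n_estimators": 50, "learning_rate": 1.0})),
        AlgorithmConfig("rfreg_default", R, "random_forest", "defaults", _rfr),
        AlgorithmConfig("rfreg_bo", R, "random_forest", "bayes_opt", _rfr,
                        SearchSpace((_dim("n_estimators", 20, 200, integer=True),
                                     _dim("max_depth", 2, 12, integer=True),
                                     _dim("min_samples_leaf", 1, 10,
                                          integer=True)),
                                    {"n_estimators": 100, "max_depth": 8,
                                     "min_samples_leaf": 1})),
        AlgorithmConfig("rfreg_shallow", R, "random_forest", "defaults",
                        lambda seed=0: _rfr(max_depth=5, seed=seed)),
        AlgorithmConfig("lasso_default", R, "lasso", "defaults", _lasso),
        AlgorithmConfig("lasso_bo", R, "lasso", "bayes_opt", _lasso,
                        SearchSpace((_dim("alpha", 1e-4, 10.0, log=True),),
                                    {"alpha": 1.0})),
        AlgorithmConfig("lasso_weak", R, "lasso", "defaults",
                        lambda seed=0: _lasso(alpha=0.01, seed=seed)),
        AlgorithmConfig("l1svm_default", R, "l1_svm", "defaults",
                        _l1svr("epsilon_insensitive")),
        AlgorithmConfig("l1svm_bo", R, "l1_svm", "bayes_opt",
                        _l1svr("epsilon_insensitive"),
                        SearchSpace((_dim("alpha", 1e-6, 1.0, log=True),
                                     _dim("epsilon", 0.01, 1.0, log=True)),
                                    {"alpha": 1e-4, "epsilon": 0.1})),
        AlgorithmConfig("l1svm_squared_default", R, "l1_svm", "defaults",
                        _l1svr("squared_epsilon_insensitive")),
        AlgorithmConfig("l1svm_squared_bo", R, "l1_svm", "bayes_opt",
                        _l1svr("squared_epsilon_insensitive"),
                        SearchSpace((_dim("alpha", 1e-6, 1.0, log=True),),
                                    {"alpha": 1e-4})),
    ]
    return cfgs


def baseline_config(task: Task) -> AlgorithmConfig:
    """Chance-level baseline: majority-class / training-mean predictor.

    Not part of the frozen registries; used for chance-calibration checks.
    """
    if task == "classification":
        return AlgorithmConfig(
            "baseline_majority", task, "baseline", "defaults",
            lambda seed=0: DummyClassifier(strategy="most_frequent"))
    return AlgorithmConfig(
        "baseline_mean", task, "baseline", "defaults",
        lambda seed=0: DummyRegressor(strategy="mean"))


def get_config(config_id: str) -> AlgorithmConfig:
    for cfg in classification_registry() + regression_registry():
        if cfg.id == config_id:
            return cfg
    if config_id == "baseline_majority":
        return baseline_config("classification")
    if config_id == "baseline_mean":
        return baseline_config("regression")
    raise KeyError(f"unknown config id {config_id!r}")
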