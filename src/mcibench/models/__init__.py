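from .base import SurvivalPredictor
from .cox import CoxFit, CoxPHModel, breslow_loglik
from .deepsurv import DeepSurvModel, DeepSurvSpec, neg_log_partial_likelihood
from .forest import RSFModel, RSFSpec, logrank_split_statistic

__all__ = [
    "SurvivalPredictor",
    "CoxFit",
    "CoxPHModel",
    "breslow_loglik",
    "DeepSurvModel",
    "DeepSurvSpec",
    "neg_log_partial_likelihood",
    "RSFModel",
    "RSFSpec",
    "logrank_split_statistic",
    "make_model",
]


def make_model(name: str, config=None, random_state=None):
    """Construct one of the three benchmark predictors by name."""
    if name == "coxph":
        dummies = config.cox_uses_dummies if config is not None else False
        return CoxPHModel(include_interactions=dummies)
    if name == "rsf":
        return RSFModel(random_state=random_state)
    if name == "deepsurv":
        return DeepSurvModel(random_state=random_state)
    raise ValueError(f"unknown model {name!r}")
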