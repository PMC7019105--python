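"""The seven normalization methods as scikit-learn style transformers."""

from __future__ import annotations

from ..data import CountMatrix, DataError, NormalizedMatrix, SpikeInReference
from .base import BaseNormalizer
from .basics import (
    BASiCSFit,
    BASiCSNormalizer,
    fit_basics,
    normalize_basics,
    simulate_basics_model,
)
from .grm import GRMFit, GRMNormalizer, fit_grm_cell, normalize_grm
from .linnorm import LinnormFit, LinnormNormalizer, normalize_linnorm
from .samstrt import SAMstrtNormalizer, normalize_samstrt
from .scnorm import (
    SCnormFit,
    SCnormNormalizer,
    check_slope_modes,
    gene_slopes,
    mode_of_slopes,
    normalize_scnorm,
    quantile_regression,
)
from .scran import ScranNormalizer, ScranPools, default_pool_sizes, normalize_scran
from .simple import SimpleNormalizer, normalize_simple

METHODS = ("simple", "samstrt", "basics", "grm", "scran", "scnorm", "linnorm")

#: methods that require spike-in rows in the count matrix
SPIKEIN_METHODS = ("samstrt", "basics", "grm")

_CLASSES = {
    "simple": SimpleNormalizer,
    "samstrt": SAMstrtNormalizer,
    "basics": BASiCSNormalizer,
    "grm": GRMNormalizer,
    "scran": ScranNormalizer,
    "scnorm": SCnormNormalizer,
    "linnorm": LinnormNormalizer,
}


def make_normalizer(method: str, **params) -> BaseNormalizer:
    """Instantiate a normalizer by name with method-specific parameters."""
    try:
        cls = _CLASSES[method]
    except KeyError:
        raise DataError(f"unknown method {method!r}; choose from {METHODS}") from None
    return cls(**params)


def normalize(
    cm: CountMatrix,
    method: str,
    ref: SpikeInReference | None = None,
    **params,
) -> tuple[NormalizedMatrix, BaseNormalizer]:
    """Normalize with the named method; returns the matrix and the estimator."""
    if method == "grm":
        params.setdefault("ref", ref)
    est = make_normalizer(method, **params)
    nm = est.fit_transform(cm)
    return nm, est


__all__ = [
    "METHODS",
    "SPIKEIN_METHODS",
    "make_normalizer",
    "normalize",
    "BaseNormalizer",
    "SimpleNormalizer",
    "normalize_simple",
    "SAMstrtNormalizer",
    "normalize_samstrt",
    "BASiCSFit",
    "BASiCSNormalizer",
    "fit_basics",
    "normalize_basics",
    "simulate_basics_model",
    "GRMFit",
    "GRMNormalizer",
    "fit_grm_cell",
    "normalize_grm",
    "ScranNormalizer",
    "ScranPools",
    "default_pool_sizes",
    "normalize_scran",
    "SCnormFit",
    "SCnormNormalizer",
    "quantile_regression",
    "mode_of_slopes",
    "gene_slopes",
    "check_slope_modes",
    "normalize_scnorm",
    "LinnormFit",
    "LinnormNormalizer",
    "normalize_linnorm",
]
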