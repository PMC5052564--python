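"""End-to-end convenience pipeline: encode sites, balance classes, rank
features, run incremental selection and evaluate the final random forest."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import undersample_negatives
from .model import MetricsReport, cross_validate
from .selection import IFSResult, incremental_feature_selection, svm_rank
from .types import SiteRecord
from .windows import WindowConfig, encode_sites


@dataclass
class PipelineResult:
    """Everything the two-step selection + evaluation produces."""

    X: pd.DataFrame
    y: np.ndarray
    ofc: list[str]
    ifs: IFSResult
    ofs: list[str]
    cv_mean: MetricsReport


def run_pipeline(proteins: list[dict], sites: list[SiteRecord],
                 cfg: WindowConfig | None = None, *,
                 undersample_ratio: float = 1.0,
                 svm_c: float = 1.0,
                 k: int = 300,
                 folds: int = 5,
                 rounds: int = 20,
                 ifs_trees: int = 10,
                 ifs_max_depth: int | None = 8,
                 ifs_max_samples: float | None = 0.33,
                 eval_trees: int = 500,
                 seed: int | None = None) -> PipelineResult:
    """Encode labeled sites, under-sample negatives 1:1, rank features by
    linear-SVM weight, run IFS over the top-k candidates, and report mean
    cross-validated performance of the forest on the selected subset."""
    labeled = [s for s in sites if s.label is not None]
    balanced = undersample_negatives(labeled, ratio=undersample_ratio, seed=seed)
    X, y = encode_sites(proteins, balanced, cfg)
    yv = y.to_numpy().astype(int)
    ranker = svm_rank(X, yv, C=svm_c)
    ofc = ranker.top_k(k)
    ifs = incremental_feature_selection(X, yv, ofc, folds=folds, rounds=rounds,
                                        seed=seed, n_trees=ifs_trees,
                                        max_depth=ifs_max_depth,
                                        max_samples=ifs_max_samples)
    _, cv_mean = cross_validate(X, yv, feature_names=ifs.ofs, folds=folds,
                                rounds=rounds, seed=seed, n_trees=eval_trees)
    return PipelineResult(X=X, y=yv, ofc=ofc, ifs=ifs, ofs=ifs.ofs, cv_mean=cv_mean)
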