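"""Log fold change of coverage between consecutive samples.

Every node and edge carries a vector over step pairs n = 1..N with entry
log(cov_n / cov_{n-1}) in the configured base (default 2, so a doubling is
+1 and thresholds phrased as "greater than 1" mean "more than doubled").
Node coverage is already floored, so node ratios are always defined; edge
traversal counts are floored at 1 here before the ratio for the same reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import CoverageTable, SeriesConfig
from .errors import GraphSVError


@dataclass
class LFCTable:
    """Per-step-pair log fold change matrices.

    ``node_lfc``/``edge_lfc``: DataFrames [step pair x node/edge-id], index
    1..N where step pair n is the change from sample n-1 to sample n.
    """

    node_lfc: pd.DataFrame
    edge_lfc: pd.DataFrame
    log_base: float


def _consecutive_log_ratio(matrix: pd.DataFrame, base: float) -> pd.DataFrame:
    values = matrix.to_numpy(dtype=float)
    if np.any(values <= 0):
        raise GraphSVError("non-positive coverage reached log ratio (floor contract)")
    ratio = np.log(values[1:] / values[:-1]) / np.log(base)
    return pd.DataFrame(
        ratio, index=range(1, len(matrix)), columns=matrix.columns
    )


def node_lfc(cov: CoverageTable, config: SeriesConfig) -> pd.DataFrame:
    """Node log fold change between consecutive samples (coverage floored upstream)."""
    return _consecutive_log_ratio(cov.node_cov, config.log_base)


def edge_lfc(cov: CoverageTable, config: SeriesConfig) -> pd.DataFrame:
    """Edge log fold change on traversal counts, floored at 1 first."""
    floored = cov.edge_cov.astype(float).clip(lower=1.0)
    return _consecutive_log_ratio(floored, config.log_base)


def compute_lfc(cov: CoverageTable, config: SeriesConfig) -> LFCTable:
    return LFCTable(
        node_lfc=node_lfc(cov, config),
        edge_lfc=edge_lfc(cov, config),
        log_base=config.log_base,
    )
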