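"""Permutation null for VIP scores, empirical FDR, and DE-probe selection.

Shuffling class labels breaks any true expression-status association, so
re-fitting the full PLS + VIP pipeline on permuted labels yields a null
distribution of VIP values. The empirical FDR for a probe with observed
VIP ``v`` compares tail counts::

    FDR(v) = min(1, E_perm[ #{null VIPs >= v} ] / #{observed VIPs >= v})

where the expectation is the mean over permutations and the null counts
pool the whole probe axis within each permutation. Closed (>=) tail
counting makes ties conservative. The raw ratios are then monotonized
with a running minimum over less-or-equally-extreme thresholds, so that a
larger VIP never carries a larger FDR (the usual q-value construction).

Probes with FDR below the threshold (strict, default 0.05) are selected
as differentially expressed; their direction is the sign of the patient
minus control mean difference on the raw log2 scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleLabels
from .pls import VIPScores, nipals_pls, vip

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationNull",
    "permutation_null",
    "empirical_fdr",
    "direction",
    "select_de",
]

DEFAULT_N_PERMUTATIONS = 10_000
DEFAULT_FDR_THRESHOLD = 0.05


@dataclass
class PermutationNull:
    """VIP values recomputed under label permutation.

    ``null_vips`` has one row per permutation and one column per probe;
    each row satisfies the VIP normalization identity except for the
    (logged) degenerate permutations recorded as all-zero rows.
    """

    null_vips: np.ndarray        # n_permutations x p
    probe_ids: list[str]
    seed: int
    n_degenerate: int = 0

    @property
    def n_permutations(self) -> int:
        return self.null_vips.shape[0]


def permutation_null(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    probe_ids: list[str] | None = None,
) -> PermutationNull:
    """Recompute VIP under uniform label shuffles of the centered response.

    X is fixed (its scaling does not depend on y); only the response is
    permuted, which preserves class sizes and keeps it centered. A
    permutation for which the model explains no response variance is
    recorded as an all-zero VIP row (conservative) and counted.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if probe_ids is None:
        probe_ids = [f"x{j}" for j in range(p)]
    rng = np.random.default_rng(seed)
    null = np.zeros((n_permutations, p))
    n_degenerate = 0
    for b in range(n_permutations):
        yb = rng.permutation(y)
        try:
            with warnings.catch_warnings():
                # early-stop warnings are summarized in the degenerate count
                warnings.simplefilter("ignore", UserWarning)
                model = nipals_pls(X, yb, n_components)
            if model.n_components == 0 or model.ssy.sum() <= 0:
                raise ValueError("degenerate permutation")
            null[b] = vip(model).vip
        except ValueError:
            n_degenerate += 1  # row stays all-zero
    if n_degenerate:
        logger.warning(
            "%d of %d permutations explained no response variance; "
            "their VIPs were recorded as zero",
            n_degenerate,
            n_permutations,
        )
    return PermutationNull(null, list(probe_ids), seed, n_degenerate)


def empirical_fdr(
    observed: VIPScores,
    null: PermutationNull,
    monotonize: bool = True,
) -> pd.Series:
    """Per-probe empirical FDR from pooled permutation tail counts.

    With ``monotonize`` (default) the raw tail-ratio estimates are
    replaced by their running minimum over all thresholds at or below
    each probe's VIP, making FDR non-increasing in VIP.
    """
    if list(observed.probe_ids) != list(null.probe_ids):
        raise ValueError("observed VIPs and permutation null cover different probes")
    v = np.asarray(observed.vip, dtype=float)
    pooled = np.sort(null.null_vips.ravel())
    B = null.n_permutations
    # closed tail counts via searchsorted on the sorted pooled null
    null_tail = pooled.size - np.searchsorted(pooled, v, side="left")
    obs_sorted = np.sort(v)
    obs_tail = v.size - np.searchsorted(obs_sorted, v, side="left")
    raw = np.minimum(1.0, (null_tail / B) / obs_tail)
    if monotonize:
        order = np.argsort(v, kind="stable")  # ascending VIP
        running = np.minimum.accumulate(raw[order])
        out = np.empty_like(raw)
        out[order] = running
        raw = out
    return pd.Series(raw, index=observed.probe_ids, name="fdr")


def direction(matrix: ExpressionMatrix, labels: SampleLabels) -> pd.Series:
    """Per-probe regulation direction: patient vs control log2 group means.

    ``up`` if the patient mean exceeds the control mean, else ``down``;
    exact ties go to ``down`` with a logged count.
    """
    if matrix.sample_ids != labels.sample_ids:
        raise ValueError("matrix and labels are not aligned; call io.align first")
    mask = labels.y == 1
    diff = matrix.values[:, mask].mean(axis=1) - matrix.values[:, ~mask].mean(axis=1)
    n_ties = int((diff == 0).sum())
    if n_ties:
        logger.warning("%d probes have exactly equal group means; labeled 'down'", n_ties)
    return pd.Series(
        np.where(diff > 0, "up", "down"), index=matrix.probe_ids, name="direction"
    )


def select_de(
    observed: VIPScores,
    fdr: pd.Series,
    direction: pd.Series,
    threshold: float = DEFAULT_FDR_THRESHOLD,
    gene_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Assemble the significance table and flag DE probes (FDR < threshold).

    The inequality is strict, so a probe at exactly the threshold is not
    selected. The table is sorted by VIP descending. ``gene_map``
    optionally attaches a gene symbol per probe.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    probes = list(observed.probe_ids)
    table = pd.DataFrame(
        {
            "probe_id": probes,
            "vip": np.asarray(observed.vip, dtype=float),
            "fdr": fdr.loc[probes].to_numpy(),
            "direction": direction.loc[probes].to_numpy(),
        }
    )
    if gene_map is not None:
        table.insert(1, "gene_id", table["probe_id"].map(gene_map))
    table["selected"] = table["fdr"] < threshold
    table = table.sort_values("vip", ascending=False, kind="stable", ignore_index=True)
    sel = table[table.selected]
    logger.info(
        "selected %d probes at FDR < %g (%d up, %d down)",
        len(sel),
        threshold,
        int((sel.direction == "up").sum()),
        int((sel.direction == "down").sum()),
    )
    return table
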