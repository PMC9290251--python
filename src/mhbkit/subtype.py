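"""Epi-cluster discovery: variance filtering, rank-2 NMF, signature extraction
and Methy-High / Methy-Low labeling.

The factorization is a multiplicative-update NMF under the Frobenius loss,
restarted from ``runs`` seeded random initializations; the run with the
smallest reconstruction error is kept. Samples are assigned to the component
with the largest coefficient, and the cluster with the higher mean
methylation over the signature blocks is labeled Methy-High (the
hypermethylated epi-cluster, which carries the worse prognosis).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .core import MHLMatrix

log = logging.getLogger("mhbkit")

METHY_HIGH = "Methy-High"
METHY_LOW = "Methy-Low"

DEFAULT_TOP_K = 20_000
DEFAULT_RANK = 2
DEFAULT_RUNS = 100
DEFAULT_SPECIFICITY = 0.75
DEFAULT_MAX_ITER = 500
DEFAULT_TOL = 1e-6


@dataclass
class NMFModel:
    """Best-of-runs non-negative factorization V ~ W @ H."""

    W: pd.DataFrame          # blocks x rank basis
    H: pd.DataFrame          # rank x samples coefficients
    error: float             # Frobenius reconstruction error of the best run
    runs: int
    seed: int

    @property
    def rank(self) -> int:
        return self.W.shape[1]


@dataclass
class SubtypeAssignment:
    """Per-sample component and Methy-High/Methy-Low label, plus signatures."""

    component: pd.Series                       # sample -> 1-based component index
    label: pd.Series                           # sample -> METHY_HIGH | METHY_LOW
    signatures: dict[int, list[str]]           # component -> signature block ids
    cluster_means: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def _as_frame(matrix: MHLMatrix | pd.DataFrame) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, MHLMatrix) else matrix


def select_top_variable(matrix: MHLMatrix | pd.DataFrame,
                        k: int = DEFAULT_TOP_K) -> pd.DataFrame:
    """Keep the k blocks with the largest sample-wise standard deviation of MHL."""
    df = _as_frame(matrix)
    if df.isna().any().any():
        raise ValueError("matrix has missing entries; run filter_missing_blocks first")
    if k < 1:
        raise ValueError("k must be >= 1")
    sd = df.std(axis=1, ddof=1)
    if k >= len(df):
        if k > len(df):
            log.warning("requested top %d blocks but only %d available", k, len(df))
        return df.loc[sd.sort_values(ascending=False, kind="stable").index]
    order = sd.sort_values(ascending=False, kind="stable").index[:k]
    return df.loc[order]


def nmf_factorize(matrix: MHLMatrix | pd.DataFrame, rank: int = DEFAULT_RANK,
                  runs: int = DEFAULT_RUNS, seed: int = 0,
                  max_iter: int = DEFAULT_MAX_ITER, tol: float = DEFAULT_TOL
                  ) -> NMFModel:
    """Multiplicative-update NMF, best of ``runs`` seeded random restarts."""
    df = _as_frame(matrix)
    if df.isna().any().any():
        raise ValueError("matrix has missing entries")
    v = df.to_numpy(dtype=float)
    if not v.any():
        raise ValueError("all-zero matrix cannot be factorized")
    if rank > min(v.shape):
        raise ValueError(f"rank {rank} exceeds min(matrix dims) {min(v.shape)}")

    # one master seed spawns a reproducible, extendable per-run seed stream
    run_seeds = np.random.SeedSequence(seed).generate_state(runs)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for rs in run_seeds:
            model = NMF(n_components=rank, solver="mu", beta_loss="frobenius",
                        init="random", max_iter=max_iter, tol=tol,
                        random_state=int(rs))
            w = model.fit_transform(v)
            if best is None or model.reconstruction_err_ < best[0]:
                best = (float(model.reconstruction_err_), w, model.components_)
    err, w, h = best
    comp = [f"C{i + 1}" for i in range(rank)]
    return NMFModel(W=pd.DataFrame(w, index=df.index, columns=comp),
                    H=pd.DataFrame(h, index=comp, columns=df.columns),
                    error=err, runs=runs, seed=seed)


def extract_component_features(model: NMFModel,
                               specificity: float = DEFAULT_SPECIFICITY
                               ) -> dict[int, list[str]]:
    """Signature blocks per component by basis-row specificity.

    Each basis row is normalized to sum 1; a block is a component's
    signature when its normalized weight on that component is at least
    ``specificity`` and its unnormalized row maximum is at least the median
    row maximum (so near-zero rows never qualify). Each block joins at most
    one component.
    """
    w = model.W.to_numpy(dtype=float)
    row_max = w.max(axis=1)
    med = float(np.median(row_max))
    sums = w.sum(axis=1)
    out: dict[int, list[str]] = {c + 1: [] for c in range(model.rank)}
    for i, bid in enumerate(model.W.index):
        if sums[i] == 0 or row_max[i] < med:
            continue
        norm = w[i] / sums[i]
        c = int(np.argmax(norm))
        if norm[c] >= specificity:
            out[c + 1].append(bid)
    return out


def assign_and_label(model: NMFModel, features: dict[int, list[str]],
                     matrix: MHLMatrix | pd.DataFrame) -> SubtypeAssignment:
    """Assign samples to their dominant component and name the clusters.

    A sample goes to the component with the largest H coefficient (ties to
    the lower index). The mean MHL over the union of signature blocks is
    computed within each cluster; the higher-mean cluster is Methy-High.
    A component with an empty signature set triggers a fallback to the mean
    over all selected blocks.
    """
    df = _as_frame(matrix)
    h = model.H.to_numpy(dtype=float)
    comp = pd.Series(np.argmax(h, axis=0) + 1, index=model.H.columns, name="component")

    union = sorted({b for blocks in features.values() for b in blocks})
    if any(not blocks for blocks in features.values()):
        log.warning("a component has no signature blocks; labeling by all blocks")
        union = []
    rows = df.loc[union] if union else df

    means = {}
    for c in range(1, model.rank + 1):
        members = comp.index[comp == c]
        means[c] = float(rows[members].to_numpy().mean()) if len(members) else -np.inf
    cluster_means = pd.Series(means)
    high = int(cluster_means.idxmax())
    label = comp.map(lambda c: METHY_HIGH if c == high else METHY_LOW)
    label.name = "label"
    return SubtypeAssignment(component=comp, label=label, signatures=features,
                             cluster_means=cluster_means)


def classify(matrix: MHLMatrix | pd.DataFrame, top_k: int = DEFAULT_TOP_K,
             rank: int = DEFAULT_RANK, runs: int = DEFAULT_RUNS, seed: int = 0,
             specificity: float = DEFAULT_SPECIFICITY) -> tuple[SubtypeAssignment, NMFModel]:
    """Full discovery recipe: variance filter -> NMF -> signatures -> labels."""
    selected = select_top_variable(matrix, k=top_k)
    model = nmf_factorize(selected, rank=rank, runs=runs, seed=seed)
    features = extract_component_features(model, specificity=specificity)
    return assign_and_label(model, features, selected), model
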