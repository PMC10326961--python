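"""Interpretation of trained models: tumour-level features, latent factors,
signature association and attention-matrix mining.

Tumour-level features are the concatenated pre-prediction logit vectors of
the ensemble components (n_components x n_classes values per tumour). They
are projected to 2-D with UMAP for subtype exploration, decomposed with
non-negative matrix factorization into latent factors, and those factor
loadings regressed against mutational-signature exposures with per-signature
ordinary least squares on log(s+1), Benjamini-Hochberg corrected across all
(signature, factor) tests.

Attention mining extracts the raw similarity matrices A = QK' from the
encoder, keeps entries above a fraction of each tumour's maximum, maps the
rows/columns back to motif and position tokens, and averages first within
tumours and then across tumours of each type.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .encoding import TokenDictionary, TokenizedCatalogue, motif_mutation_group
from .model import MutationSetClassifier
from .training import EnsembleModel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Tumour-level features
# ---------------------------------------------------------------------------


def extract_features(
    ensemble: EnsembleModel,
    catalogues: Sequence[TokenizedCatalogue],
    seed: int = 0,
) -> pd.DataFrame:
    """One row per sample; columns are component x class logits, fixed order."""
    labels = ensemble.class_labels or [str(i) for i in range(ensemble.components[0].config.n_classes)]
    cols = [f"c{ci}_{lab}" for ci in range(ensemble.n_components) for lab in labels]
    rows, idx = [], []
    for tc in catalogues:
        rows.append(ensemble.component_logits(tc, seed=seed).ravel())
        idx.append(tc.sample_id)
    return pd.DataFrame(rows, index=idx, columns=cols)


def project_2d(
    features: pd.DataFrame,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> pd.DataFrame:
    """UMAP projection of the feature matrix onto two dimensions."""
    if len(features) < 3:
        raise ValueError("need at least 3 samples to project")
    if n_neighbors >= len(features):
        n_neighbors = len(features) - 1
        logger.warning("n_neighbors reduced to %d (more neighbours than samples)", n_neighbors)
    import umap

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed)
        coords = reducer.fit_transform(features.to_numpy(dtype=float))
    return pd.DataFrame(coords, index=features.index, columns=["umap1", "umap2"])


# ---------------------------------------------------------------------------
# Non-negative factorization of features
# ---------------------------------------------------------------------------


@dataclass
class Factorization:
    """NMF of the (min-shifted) feature matrix: X + shift ~ W @ H."""

    W: pd.DataFrame  # samples x k loadings
    H: pd.DataFrame  # k x features basis
    shift: np.ndarray  # per-column shift applied to make X non-negative
    reconstruction_error: float
    k: int


def _shift_nonnegative(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mins = X.min(axis=0)
    shift = np.where(mins < 0, -mins, 0.0)
    return X + shift, shift


def nmf_factorize(
    features: pd.DataFrame,
    k: int = 50,
    seed: int = 0,
    max_iter: int = 2000,
) -> Factorization:
    """Rank-k NMF minimizing the Frobenius norm (scikit-learn backend).

    Feature logits can be negative, so each column is shifted by its minimum
    first; the shift is stored so factors stay comparable across runs.
    """
    X = features.to_numpy(dtype=float)
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds matrix rank bound {min(X.shape)}")
    Xs, shift = _shift_nonnegative(X)
    from sklearn.decomposition import NMF

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nmf = NMF(n_components=k, init="nndsvda", random_state=seed,
                  max_iter=max_iter, beta_loss="frobenius")
        W = nmf.fit_transform(Xs)
    H = nmf.components_
    err = float(np.linalg.norm(Xs - W @ H, "fro"))
    factor_names = [f"M{i + 1}" for i in range(k)]
    return Factorization(
        W=pd.DataFrame(W, index=features.index, columns=factor_names),
        H=pd.DataFrame(H, index=factor_names, columns=features.columns),
        shift=shift,
        reconstruction_error=err,
        k=k,
    )


def reconstruction_curve(
    features: pd.DataFrame, k_list: Sequence[int], seed: int = 0, max_iter: int = 2000
) -> pd.DataFrame:
    """Reconstruction-error-vs-k curve for knee analysis."""
    rows = [
        {"k": k, "reconstruction_error": nmf_factorize(features, k, seed, max_iter).reconstruction_error}
        for k in k_list
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Signature association
# ---------------------------------------------------------------------------


def associate_signatures(
    W: pd.DataFrame,
    exposures: pd.DataFrame,
    fdr: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """OLS of log(s+1) on all factors, per signature, with BH-FDR flags.

    Returns (coefficient table, per-signature R^2 table). The coefficient
    table has one row per (signature, factor) with coefficient, p-value,
    q-value and a significance flag at the requested FDR. Collinear factors
    are dropped with a warning.
    """
    import statsmodels.api as sm
    from statsmodels.stats.multitest import multipletests

    if not W.index.equals(exposures.index):
        exposures = exposures.loc[W.index]
    X = W.to_numpy(dtype=float)
    keep = list(W.columns)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X]))
    if rank < X.shape[1] + 1:
        # drop factors that do not increase design rank
        cols, base = [], np.ones((len(X), 1))
        for j, name in enumerate(W.columns):
            trial = np.column_stack([base] + [X[:, c] for c in cols] + [X[:, j]])
            if np.linalg.matrix_rank(trial) > 1 + len(cols):
                cols.append(j)
            else:
                logger.warning("dropping collinear factor %s", name)
        keep = [W.columns[j] for j in cols]
        X = X[:, cols]

    rows, rsq_rows = [], []
    design = sm.add_constant(X, has_constant="add")
    for sig in exposures.columns:
        s = exposures[sig].to_numpy(dtype=float)
        if (s < 0).any():
            raise ValueError(f"negative exposure counts for {sig}")
        y = np.log(s + 1.0)
        if np.allclose(y, 0.0):
            for name in keep:
                rows.append({"signature": sig, "factor": name, "coefficient": 0.0, "p_value": 1.0})
            rsq_rows.append({"signature": sig, "r_squared": 0.0})
            continue
        fit = sm.OLS(y, design).fit()
        for j, name in enumerate(keep, start=1):
            rows.append({
                "signature": sig,
                "factor": name,
                "coefficient": float(fit.params[j]),
                "p_value": float(fit.pvalues[j]) if np.isfinite(fit.pvalues[j]) else 1.0,
            })
        rsq_rows.append({"signature": sig, "r_squared": float(fit.rsquared)})
    coef = pd.DataFrame(rows)
    reject, qvals, _, _ = multipletests(coef["p_value"], alpha=fdr, method="fdr_bh")
    coef["q_value"] = qvals
    coef["significant"] = reject
    return coef, pd.DataFrame(rsq_rows)


# ---------------------------------------------------------------------------
# Attention-matrix mining
# ---------------------------------------------------------------------------


@dataclass
class AttentionSummary:
    motif_pairs: pd.DataFrame      # class, query_motif, key_motif, mean value
    position_pairs: pd.DataFrame   # class, query_bin, key_bin, mean value
    type_composition: pd.DataFrame  # class, query_type, key_type, fraction
    per_tumour_retained: pd.DataFrame


def threshold_entries(A: np.ndarray, threshold_frac: float = 0.9):
    """Indices and values of entries strictly above threshold_frac * max(A)."""
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must be in (0, 1)")
    A = np.asarray(A, dtype=float)
    cutoff = threshold_frac * A.max()
    rows, cols = np.where(A > cutoff)
    return rows, cols, A[rows, cols]


def attention_summary(
    model: MutationSetClassifier,
    catalogues: Sequence[TokenizedCatalogue],
    dicts: Mapping[str, TokenDictionary],
    threshold_frac: float = 0.9,
    layer: int = 0,
    head: int = 0,
    variant: str = "raw",
) -> AttentionSummary:
    """Mine the attention matrices of a single (non-ensemble) model.

    Per tumour, A = QK' (raw by default) is thresholded at
    ``threshold_frac * max(A)`` (per-tumour maximum); retained entries are
    mapped back to motif and position tokens, averaged within the tumour per
    (query, key) pair, then averaged across the tumours of each class.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must be in (0, 1)")
    motif_d, pos_d = dicts["motif"], dicts["position"]

    per_class_motif: dict = defaultdict(lambda: defaultdict(list))
    per_class_pos: dict = defaultdict(lambda: defaultdict(list))
    per_class_types: dict = defaultdict(lambda: defaultdict(int))
    retained_rows = []

    for tc in catalogues:
        A = model.attention_scores(tc.tokens(), layer=layer, head=head, variant=variant)
        rows, cols, vals = threshold_entries(A, threshold_frac)
        label = tc.class_label or "unlabelled"
        retained_rows.append({"sample_id": tc.sample_id, "class": label, "n_retained": len(vals)})
        motif_acc: dict = defaultdict(list)
        pos_acc: dict = defaultdict(list)
        for r, c, v in zip(rows, cols, vals):
            qm = motif_d.token(int(tc.motif_idx[r]))
            km = motif_d.token(int(tc.motif_idx[c]))
            qp = pos_d.token(int(tc.position_idx[r]))
            kp = pos_d.token(int(tc.position_idx[c]))
            motif_acc[(qm, km)].append(v)
            pos_acc[(qp, kp)].append(v)
            per_class_types[label][(motif_mutation_group(qm), motif_mutation_group(km))] += 1
        for pair, vs in motif_acc.items():  # mean within tumour first
            per_class_motif[label][pair].append(float(np.mean(vs)))
        for pair, vs in pos_acc.items():
            per_class_pos[label][pair].append(float(np.mean(vs)))

    def _collect(per_class, q_name, k_name):
        recs = [
            {"class": label, q_name: pair[0], k_name: pair[1], "value": float(np.mean(vs)),
             "n_tumours": len(vs)}
            for label, pairs in per_class.items()
            for pair, vs in pairs.items()
        ]
        df = pd.DataFrame(recs, columns=["class", q_name, k_name, "value", "n_tumours"])
        return df.sort_values(["class", "value"], ascending=[True, False]).reset_index(drop=True)

    type_recs = []
    for label, pairs in per_class_types.items():
        total = sum(pairs.values())
        for (qt, kt), cnt in pairs.items():
            type_recs.append({"class": label, "query_type": qt, "key_type": kt,
                              "count": cnt, "fraction": cnt / total})
    return AttentionSummary(
        motif_pairs=_collect(per_class_motif, "query_motif", "key_motif"),
        position_pairs=_collect(per_class_pos, "query_bin", "key_bin"),
        type_composition=pd.DataFrame(
            type_recs, columns=["class", "query_type", "key_type", "count", "fraction"]
        ),
        per_tumour_retained=pd.DataFrame(retained_rows),
    )
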