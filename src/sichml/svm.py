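"""Soft-margin SVM with per-sample box constraints proportional to NIHSS.

The classifier at the heart of the pipeline is a standard two-class
soft-margin SVM with one twist: instead of a single penalty parameter C,
every training subject i has its own cap C_i on the dual coefficient,
set proportional to that subject's baseline stroke severity (NIHSS).  A
severe stroke thereby contributes more to the decision boundary than a mild
one — clinical severity enters the model through the margin penalties
rather than as an extra feature.

The dual problem

    min_a  1/2 a' Q a - 1' a,   Q_ij = y_i y_j k(x_i, x_j)
    s.t.   0 <= a_i <= C_i,     sum_i a_i y_i = 0

is solved by sequential minimal optimization with maximal-violating-pair
working-set selection.  An indefinite (tanh) kernel is accepted by flooring
the pair curvature, which keeps every update a bounded descent step; a
finite iteration budget guarantees termination, with non-convergence
reported in the model diagnostics rather than raised.

Sign convention used throughout the pipeline: SICH subjects are labelled
-1, so a *negative* decision value reads "SICH-like".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from sichml.cohort import ClinicalRecord, ConsensusReading, Outcome


class KernelKind(str, Enum):
    LINEAR = "linear"
    SIGMOID_MLP = "sigmoid_mlp"
    RBF = "rbf"


@dataclass(frozen=True)
class KernelSpec:
    """k(u,v) = <u,v> (linear); tanh(scale <u,v> + offset) (sigmoid);
    exp(-gamma ||u-v||^2) (RBF)."""

    kind: KernelKind = KernelKind.LINEAR
    scale: float = 1.0
    offset: float = -1.0
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.kind == KernelKind.SIGMOID_MLP and self.scale <= 0:
            raise ValueError("sigmoid kernel requires scale > 0")
        if self.kind == KernelKind.RBF and (self.gamma is None or self.gamma <= 0):
            raise ValueError("RBF kernel requires gamma > 0")


def kernel_matrix(spec: KernelSpec, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if spec.kind == KernelKind.LINEAR:
        return A @ B.T
    if spec.kind == KernelKind.SIGMOID_MLP:
        return np.tanh(spec.scale * (A @ B.T) + spec.offset)
    sq = (np.sum(A**2, axis=1)[:, None] + np.sum(B**2, axis=1)[None, :]
          - 2.0 * A @ B.T)
    return np.exp(-spec.gamma * np.maximum(sq, 0.0))


@dataclass
class SvmModel:
    kernel: KernelSpec
    support_vectors: np.ndarray     # (n_sv, d)
    dual_coefs: np.ndarray          # alpha_i * y_i at support vectors
    bias: float
    per_sample_cap: np.ndarray      # caps of the support vectors
    sign_convention: str = "negative distance = SICH-like"
    n_features: int = 0
    feature_center: np.ndarray | None = None
    feature_scale: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)


def nihss_to_caps(nihss: Sequence[float], base_c: float = 1.0) -> np.ndarray:
    """Mean-normalized proportional caps: C_i = base_c * NIHSS_i / mean(NIHSS),
    with zero-NIHSS subjects floored at 0.01 * base_c so no subject drops out
    of the model entirely."""
    nihss = np.asarray(nihss, dtype=float)
    if base_c <= 0:
        raise ValueError("base_c must be positive")
    if np.any(nihss < 0):
        raise ValueError("NIHSS must be non-negative")
    mean = nihss.mean()
    if mean == 0:
        raise ValueError("all-zero NIHSS vector cannot be scaled")
    caps = base_c * nihss / mean
    return np.maximum(caps, 0.01 * base_c)


def _smo(K: np.ndarray, y: np.ndarray, caps: np.ndarray,
         tol: float, max_iter: int) -> tuple[np.ndarray, float, dict]:
    n = len(y)
    alpha = np.zeros(n)
    # f_i = sum_j alpha_j y_j K_ij (decision value without bias)
    f = np.zeros(n)
    it = 0
    while it < max_iter:
        it += 1
        E = f - y
        up = ((y > 0) & (alpha < caps)) | ((y < 0) & (alpha > 0))
        low = ((y < 0) & (alpha < caps)) | ((y > 0) & (alpha > 0))
        neg_E = -E
        m_val = np.max(neg_E[up])
        M_val = np.min(neg_E[low])
        if m_val - M_val < tol:
            break
        i = int(np.flatnonzero(up)[np.argmax(neg_E[up])])
        j = int(np.flatnonzero(low)[np.argmin(neg_E[low])])

        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        eta = max(eta, 1e-12)       # floor for indefinite kernels
        aj_new = alpha[j] + y[j] * (E[i] - E[j]) / eta
        if y[i] != y[j]:
            L = max(0.0, alpha[j] - alpha[i])
            H = min(caps[j], caps[i] + alpha[j] - alpha[i])
        else:
            L = max(0.0, alpha[i] + alpha[j] - caps[i])
            H = min(caps[j], alpha[i] + alpha[j])
        aj_new = min(max(aj_new, L), H)
        ai_new = alpha[i] + y[i] * y[j] * (alpha[j] - aj_new)
        # snap to the box so bound status is exact (keeps the working sets
        # consistent; otherwise float error strands a coefficient a hair
        # inside its cap and blocks the maximal violating pair)
        for idx_, a_ in ((i, ai_new), (j, aj_new)):
            if a_ < 1e-10 * caps[idx_]:
                a_ = 0.0
            elif a_ > caps[idx_] * (1 - 1e-10):
                a_ = caps[idx_]
            if idx_ == i:
                ai_new = a_
            else:
                aj_new = a_
        di, dj = ai_new - alpha[i], aj_new - alpha[j]
        if abs(dj) < 1e-14 and abs(di) < 1e-14:
            # clipped to a corner; treat as converged enough to stop
            break
        alpha[i], alpha[j] = ai_new, aj_new
        f += di * y[i] * K[:, i] + dj * y[j] * K[:, j]

    E = f - y
    free = (alpha > 1e-8 * caps) & (alpha < caps * (1 - 1e-8))
    if free.any():
        bias = float(np.mean(-E[free]))
    else:
        up = ((y > 0) & (alpha < caps)) | ((y < 0) & (alpha > 0))
        low = ((y < 0) & (alpha < caps)) | ((y > 0) & (alpha > 0))
        bias = float(0.5 * (np.max(-E[up]) + np.min(-E[low])))
    up = ((y > 0) & (alpha < caps)) | ((y < 0) & (alpha > 0))
    low = ((y < 0) & (alpha < caps)) | ((y > 0) & (alpha > 0))
    violation = float(np.max(-E[up]) - np.min(-E[low]))
    diag = {"iterations": it, "converged": violation < tol,
            "kkt_violation": violation}
    return alpha, bias, diag


def train_svm(features: np.ndarray, labels: Sequence[int],
              caps: np.ndarray | float = 1.0,
              kernel: KernelSpec = KernelSpec(),
              seed: int = 0,
              tol: float = 1e-3,
              max_iter: int | None = None,
              gram: np.ndarray | None = None) -> SvmModel:
    """Train the per-sample-cap SVM.

    ``caps`` may be a scalar (ordinary C-SVM) or one cap per subject.  The
    solve is deterministic given the input order; ``seed`` is accepted for
    interface symmetry with the stochastic stages but unused, as working-set
    selection is by maximal KKT violation with lowest-index tie-breaks.
    ``gram`` may supply a precomputed kernel matrix of the training rows to
    avoid recomputation across many overlapping splits.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ValueError("labels must be +-1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    caps = np.broadcast_to(np.asarray(caps, dtype=float), y.shape).copy()
    if np.any(caps <= 0):
        raise ValueError("caps must be positive")
    K = kernel_matrix(kernel, X, X) if gram is None else np.asarray(gram, dtype=float)
    if max_iter is None:
        max_iter = max(200 * len(y), 20000)
    alpha, bias, diag = _smo(K, y, caps, tol, max_iter)

    sv = alpha > 1e-10 * caps.max()
    model = SvmModel(
        kernel=kernel,
        support_vectors=X[sv],
        dual_coefs=alpha[sv] * y[sv],
        bias=bias,
        per_sample_cap=caps[sv],
        n_features=X.shape[1],
        diagnostics=diag,
    )
    model.diagnostics["n_support"] = int(sv.sum())
    model.diagnostics["alpha"] = alpha
    return model


def decision_distance(model: SvmModel, x: np.ndarray) -> np.ndarray | float:
    """Signed distance to the hyperplane (arbitrary units):
    f(x) = sum_i dual_coef_i k(sv_i, x) + bias.  Negative reads SICH-like
    under the pipeline's labelling."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match the model's "
            f"{model.n_features} (different retained-voxel set?)")
    if model.feature_center is not None:
        X = (X - model.feature_center) / model.feature_scale
    K = kernel_matrix(model.kernel, X, model.support_vectors)
    f = K @ model.dual_coefs + model.bias
    return float(f[0]) if single else f


# ---------------------------------------------------------------------------
# manual SVM on radiology features

def manual_features(records: Sequence[ClinicalRecord],
                    consensuses: Sequence[ConsensusReading]) -> np.ndarray:
    """(NIHSS, ischemia extent 0/1/2, hyperdense MCA 0/1) per subject."""
    rows = []
    for r, c in zip(records, consensuses):
        extent = (2 if c.gt_third_mca else 1) if c.acute_ischemia else 0
        rows.append([float(r.nihss), float(extent), float(c.hyperdense_mca)])
    return np.asarray(rows)


def outcome_labels(records: Sequence[ClinicalRecord]) -> np.ndarray:
    """-1 for SICH, +1 for non-SICH (so negative decisions are SICH-like)."""
    return np.array([-1.0 if r.outcome == Outcome.SICH else 1.0 for r in records])


def train_manual_svm(records: Sequence[ClinicalRecord],
                     consensuses: Sequence[ConsensusReading],
                     caps: np.ndarray | None = None,
                     kernel: KernelSpec = KernelSpec(),
                     seed: int = 0) -> SvmModel:
    """The 'manual' alternative: standardized (NIHSS, ischemia extent,
    hyperdense MCA) features instead of whole images.  Standardization is
    stored on the model and applied by :func:`decision_distance`."""
    X = manual_features(records, consensuses)
    y = outcome_labels(records)
    if caps is None:
        caps = nihss_to_caps([r.nihss for r in records])
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    model = train_svm((X - center) / scale, y, caps=caps, kernel=kernel, seed=seed)
    model.feature_center = center
    model.feature_scale = scale
    return model


# ---------------------------------------------------------------------------
# ablations

class AblationVariant(str, Enum):
    NO_NIHSS = "no_nihss"
    NO_BASE = "no_base"
    SINGLE_HEMISPHERE = "single_hemisphere"


def base_section_column_mask(voxel_index: np.ndarray, upper_start: int) -> np.ndarray:
    """True for voxel columns sampled only by the brain-base section
    (common-grid z below the start of the upper section)."""
    return np.asarray(voxel_index)[:, 2] < upper_start


def hemisphere_features(values: np.ndarray, voxel_index: np.ndarray,
                        nx: int, lesion_sides: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject lesion-side hemisphere features on a shared column basis.

    Keeps left-half voxels whose x-mirror is also retained; subjects with a
    right-sided lesion contribute the mirrored column.  Returns the reduced
    matrix and the (left-half) voxel index it is defined on.
    """
    from sichml.cohort import Side

    vi = np.asarray(voxel_index)
    coord_to_col = {tuple(c): i for i, c in enumerate(vi.tolist())}
    left_cols, right_cols, kept_index = [], [], []
    for i, (x, y, z) in enumerate(vi.tolist()):
        if x >= nx / 2:
            continue
        mirror = (nx - 1 - x, y, z)
        j = coord_to_col.get(mirror)
        if j is None:
            continue
        left_cols.append(i)
        right_cols.append(j)
        kept_index.append((x, y, z))
    if not left_cols:
        raise ValueError("empty feature set after hemisphere masking")
    left_cols = np.asarray(left_cols)
    right_cols = np.asarray(right_cols)
    out = np.empty((values.shape[0], len(left_cols)))
    for s, side in enumerate(lesion_sides):
        cols = left_cols if side == Side.LEFT else right_cols
        out[s] = values[s, cols]
    return out, np.asarray(kept_index, dtype=np.int32)


def ablate(variant: AblationVariant,
           values: np.ndarray,
           labels: np.ndarray,
           nihss: Sequence[float],
           voxel_index: np.ndarray,
           kernel: KernelSpec = KernelSpec(),
           base_c: float = 1.0,
           upper_start: int | None = None,
           nx: int | None = None,
           lesion_sides: Sequence | None = None,
           seed: int = 0) -> tuple[SvmModel, dict]:
    """Train one of the three model variants: uniform caps (severity removed
    from the soft margin), brain-base voxels excluded, or lesion-side
    hemisphere only."""
    variant = AblationVariant(variant)
    info: dict = {"variant": variant.value}
    if variant == AblationVariant.NO_NIHSS:
        caps = np.full(len(labels), base_c)
        X = values
        info["voxel_index"] = np.asarray(voxel_index)
    elif variant == AblationVariant.NO_BASE:
        if upper_start is None:
            raise ValueError("NO_BASE requires upper_start")
        drop = base_section_column_mask(voxel_index, upper_start)
        if np.all(drop):
            raise ValueError("empty feature set after removing base section")
        X = values[:, ~drop]
        caps = nihss_to_caps(nihss, base_c)
        info["voxel_index"] = np.asarray(voxel_index)[~drop]
    else:
        if nx is None or lesion_sides is None:
            raise ValueError("SINGLE_HEMISPHERE requires nx and lesion_sides")
        X, kept = hemisphere_features(values, voxel_index, nx, lesion_sides)
        caps = nihss_to_caps(nihss, base_c)
        info["voxel_index"] = kept
    info["n_features"] = X.shape[1]
    model = train_svm(X, labels, caps=caps, kernel=kernel, seed=seed)
    return model, info
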