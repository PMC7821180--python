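"""Independent plain-loop reference of similarity network fusion.

Transcribed directly from the published cross-diffusion method (full-kernel
status matrices, KNN local kernels, P_v <- S_v (sum_{w!=v} P_w)/(V-1) S_v^T,
identity regularization and a final average), written with explicit Python
loops and the original regularization convention.  Used only as a
cross-check oracle for the library implementation; numerical conventions
differ slightly, so agreement is asserted as a high off-diagonal
correlation rather than bit-equality.
"""

import numpy as np


def _full_kernel_loops(w: np.ndarray) -> np.ndarray:
    p = w.shape[0]
    out = np.zeros((p, p))
    for i in range(p):
        denom = 0.0
        for t in range(p):
            if t != i:
                denom += w[i, t]
        for j in range(p):
            if j == i:
                out[i, j] = 0.5
            elif denom > 0:
                out[i, j] = w[i, j] / (2.0 * denom)
    return out


def _knn_kernel_loops(w: np.ndarray, k: int) -> np.ndarray:
    p = w.shape[0]
    out = np.zeros((p, p))
    for i in range(p):
        order = sorted((j for j in range(p) if j != i), key=lambda j: (-w[i, j], j))
        neighbours = order[:k]
        mass = sum(w[i, j] for j in neighbours)
        for j in neighbours:
            out[i, j] = w[i, j] / mass if mass > 0 else 1.0 / k
    return out


def reference_snf(matrices: list, K: int = 20, T: int = 20, alpha: float = 1.0) -> np.ndarray:
    """Fused network per the original convention (+alpha*I regularization)."""
    status = [_full_kernel_loops(np.asarray(w, dtype=float)) for w in matrices]
    status = [(p + p.T) / 2.0 for p in status]
    local = [_knn_kernel_loops(np.asarray(w, dtype=float), K) for w in matrices]
    v = len(matrices)
    n = status[0].shape[0]
    for _ in range(T):
        updated = []
        for a in range(v):
            others = np.zeros((n, n))
            for b in range(v):
                if b != a:
                    others += status[b]
            others /= v - 1
            p_new = local[a] @ others @ local[a].T
            p_new = p_new + alpha * np.eye(n)
            updated.append((p_new + p_new.T) / 2.0)
        status = updated
    fused = np.zeros((n, n))
    for p_mat in status:
        fused += p_mat
    fused /= v
    # final row normalization as in the original release
    fused = fused / fused.sum(axis=1, keepdims=True)
    return (fused + fused.T) / 2.0
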