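"""Pattern-count selection: Monte-Carlo cross-validated PRESS and the
Van der Voet randomization test.

Repeated random holdouts (default: many independent test sets of 10% of the
participants) are used to score rank-k predictions of the standardized
responses for every candidate k, accumulating the predicted residual sum of
squares (PRESS). k = 0 — predicting every standardized response by the
training mean — is a first-class candidate, so "no useful pattern" is a
possible outcome. The chosen count is the smallest k whose PRESS is not
significantly worse than the PRESS-minimizing k, judged by Van der Voet's
paired sign-flip randomization test on per-cell squared errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PressCurve:
    """PRESS by candidate factor count, with randomization p-values."""

    press: np.ndarray  # (k_max + 1,), index = k
    p_values: np.ndarray  # vs the PRESS-minimizing k; p[ref_k] = 1
    ref_k: int  # argmin PRESS
    n_splits: int
    test_fraction: float
    n_cells: int  # held-out cells aggregated per candidate
    cell_errors: np.ndarray | None = None  # (k_max + 1, n_cells), optional

    @property
    def k_max(self) -> int:
        return len(self.press) - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": np.arange(len(self.press)), "press": self.press, "p_value": self.p_values}
        ).set_index("k")


def press_curve(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    k_max: int,
    n_splits: int = 1000,
    test_fraction: float = 0.1,
    seed: int | np.random.SeedSequence = 0,
    n_randomizations: int = 2000,
    keep_cell_errors: bool = False,
) -> PressCurve:
    """Monte-Carlo cross-validated PRESS for k = 0..k_max.

    Each split holds out ``test_fraction`` of the rows; foods and responses
    are standardized with training means/SDs only, the full OLS coefficient
    matrix and fitted-response eigenvectors are estimated on the training
    rows, and held-out standardized responses are predicted by the rank-k
    regression for every k at once. Deterministic given ``seed``.
    """
    Xv = X.to_numpy(dtype=float)
    Yv = Y.to_numpy(dtype=float)
    n, p = Xv.shape
    q = Yv.shape[1]
    if k_max > min(p, q):
        raise ValueError(f"k_max={k_max} exceeds min(p={p}, q={q})")
    n_test = max(1, int(round(n * test_fraction)))
    n_train = n - n_test
    if n_train <= p:
        raise ValueError(
            f"training rows ({n_train}) must exceed the number of foods ({p}); "
            "lower test_fraction or k_max the food count"
        )
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    split_seed, vdv_seed = ss.spawn(2)
    rng = np.random.default_rng(split_seed)

    n_cells = n_splits * n_test * q
    errors = np.empty((k_max + 1, n_cells))
    pos = 0
    for _ in range(n_splits):
        perm = rng.permutation(n)
        test, train = perm[:n_test], perm[n_test:]
        Xtr, Xte = Xv[train], Xv[test]
        Ytr, Yte = Yv[train], Yv[test]
        xm, xs = Xtr.mean(0), Xtr.std(0, ddof=1)
        ym, ys = Ytr.mean(0), Ytr.std(0, ddof=1)
        if (xs <= 0).any() or (ys <= 0).any():
            raise ValueError("constant column within a training split")
        Xtr = (Xtr - xm) / xs
        Xte = (Xte - xm) / xs
        Ytr = (Ytr - ym) / ys
        Yte = (Yte - ym) / ys
        B = np.linalg.lstsq(Xtr, Ytr, rcond=None)[0]
        Yhat = Xtr @ B
        _, vecs = np.linalg.eigh(Yhat.T @ Yhat)
        V = vecs[:, ::-1]  # descending eigenvalue order
        base = Xte @ B  # full-rank prediction
        block = slice(pos, pos + n_test * q)
        errors[0, block] = (Yte**2).ravel()
        for k in range(1, k_max + 1):
            Vk = V[:, :k]
            pred = base @ Vk @ Vk.T
            errors[k, block] = ((Yte - pred) ** 2).ravel()
        pos += n_test * q
    press = errors.sum(axis=1)
    ref_k = int(np.argmin(press))
    pvals = np.ones(k_max + 1)
    vdv_children = vdv_seed.spawn(k_max + 1)
    for k in range(k_max + 1):
        if k == ref_k:
            continue
        pvals[k] = vandervoet_test(
            errors[k], errors[ref_k], n_randomizations=n_randomizations, seed=vdv_children[k]
        )
    return PressCurve(
        press=press,
        p_values=pvals,
        ref_k=ref_k,
        n_splits=n_splits,
        test_fraction=test_fraction,
        n_cells=n_cells,
        cell_errors=errors if keep_cell_errors else None,
    )


def vandervoet_test(
    cell_errors_k: np.ndarray,
    cell_errors_ref: np.ndarray,
    n_randomizations: int = 2000,
    seed: int | np.random.SeedSequence = 0,
) -> float:
    """Van der Voet's paired sign-flip randomization test.

    The statistic is the mean paired difference of per-cell squared
    prediction errors; the null distribution is built by flipping the sign
    of each difference independently. Returns the add-one p-value
    (1 + #{|T*| >= |T|}) / (1 + n_randomizations), whose floor is
    1 / (1 + n_randomizations).
    """
    e1 = np.asarray(cell_errors_k, dtype=float)
    e2 = np.asarray(cell_errors_ref, dtype=float)
    if e1.shape != e2.shape:
        raise ValueError(f"paired error vectors differ in length: {e1.shape} vs {e2.shape}")
    d = e1 - e2
    m = d.size
    T = abs(d.mean())
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, min(n_randomizations, int(2e7) // max(m, 1)))
    done = 0
    while done < n_randomizations:
        b = min(chunk, n_randomizations - done)
        signs = rng.integers(0, 2, size=(b, m)).astype(np.float64)
        signs = 2.0 * signs - 1.0
        Ts = np.abs(signs @ d) / m
        hits += int((Ts >= T).sum())
        done += b
    return (1 + hits) / (1 + n_randomizations)


def choose_n_patterns(curve: PressCurve, alpha: float = 0.10) -> int:
    """Smallest k whose PRESS is not significantly worse than the minimum."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    for k in range(curve.k_max + 1):
        if curve.p_values[k] >= alpha:
            return k
    return curve.ref_k
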