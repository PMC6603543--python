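"""Agreement statistics between system scores and reference ratings."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_SCORES = 5  # UPDRS finger-tapping scores 0..4


@dataclass
class AgreementReport:
    confusion: np.ndarray  # (5, 5) counts, rows = reference, cols = system
    accuracy: float        # percent of equally assigned scores
    kappa: float
    n: int


def _validate(ref, sys) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(ref)
    sys = np.asarray(sys)
    if ref.shape != sys.shape or ref.ndim != 1:
        raise ValueError(f"score lists must be 1-D and equal length, got {ref.shape} vs {sys.shape}")
    for name, arr in (("reference", ref), ("system", sys)):
        if not np.all(np.isin(arr, range(N_SCORES))):
            raise ValueError(f"{name} scores must be integers in 0..{N_SCORES - 1}")
    return ref.astype(int), sys.astype(int)


def cohen_kappa(rater_a, rater_b) -> float:
    """Unweighted Cohen's kappa, (po - pe) / (1 - pe).

    When both raters are constant and identical, pe = 1 and kappa is defined
    as 1 by convention (perfect, if trivial, agreement).
    """
    a, b = _validate(rater_a, rater_b)
    if a.size < 2:
        raise ValueError("need at least 2 ratings")
    n = a.size
    po = float(np.mean(a == b))
    pe = float(
        sum(np.sum(a == k) * np.sum(b == k) for k in range(N_SCORES)) / (n * n)
    )
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)


def confusion_and_accuracy(ref, sys) -> AgreementReport:
    """5x5 confusion matrix, accuracy (%) and Cohen's kappa."""
    r, s = _validate(ref, sys)
    confusion = np.zeros((N_SCORES, N_SCORES), dtype=int)
    np.add.at(confusion, (r, s), 1)
    accuracy = 100.0 * np.trace(confusion) / r.size
    return AgreementReport(
        confusion=confusion, accuracy=float(accuracy), kappa=cohen_kappa(r, s), n=int(r.size)
    )
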