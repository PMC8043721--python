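"""Cross-validated model comparison and the composite Bayes factor.

Competing parameter-sharing schemes are compared by four-fold
cross-validation: each fold's complement (three quarters of the
observations, stratified within subject) is the calibration set on which
parameters are estimated by ML; the held-out quarter is the validation set
scored with frozen parameters.  The composite Bayes factor K = K1 * K2
combines a BIC-penalized calibration component with a validation
likelihood-ratio component.

Two sign conventions for log K1 are provided.  ``"printed"`` follows the
published equation verbatim::

    log K1 = LLcal(M2) - LLcal(M1) - (k1 - k2) ln(Ncal)
    log K2 = LLval(M1) - LLval(M2)

``"bic"`` is the half-BIC-difference orientation that reproduces published
comparison tables, where positive values favor the reference model M1::

    log K1 = (BICcal(M2) - BICcal(M1)) / 2
    log K2 = LLval(M1) - LLval(M2)

Both give exactly 0 when a model is compared against itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DataError
from .llo import LinearLogOddsModel, LLOResults, ModelSpec, bic


class ParameterError(ValueError):
    pass


def kfold_partition(
    subject: np.ndarray, folds: int = 4, seed: int = 0, stratified: bool = True
) -> np.ndarray:
    """Assign observations to folds, stratified within subject by default.

    Stratification keeps every subject present in every calibration set,
    which per-subject parameter schemes require.  Deterministic under seed.
    """
    subject = np.asarray(subject)
    rng = np.random.default_rng(seed)
    assign = np.empty(len(subject), dtype=int)
    if stratified:
        for s in pd.unique(subject):
            idx = np.flatnonzero(subject == s)
            if len(idx) < folds:
                raise DataError(
                    f"subject {s!r} has {len(idx)} observations, fewer than "
                    f"{folds} folds"
                )
            perm = rng.permutation(len(idx))
            assign[idx] = perm % folds
    else:
        if len(subject) < folds:
            raise DataError("fewer observations than folds")
        assign[:] = rng.permutation(len(subject)) % folds
    return assign


def composite_log_bayes_factor(
    llcal_m1: float,
    llcal_m2: float,
    llval_m1: float,
    llval_m2: float,
    k1: int,
    k2: int,
    n_cal: int,
    convention: str = "printed",
) -> tuple[float, float, float]:
    """Components (log K1, log K2) and their sum for models M1 vs M2."""
    if n_cal < 1:
        raise ParameterError(f"Ncal must be >= 1, got {n_cal}")
    log_n = math.log(n_cal)
    if convention == "printed":
        log_k1 = llcal_m2 - llcal_m1 - (k1 - k2) * log_n
    elif convention == "bic":
        log_k1 = 0.5 * (bic(llcal_m2, k2, n_cal) - bic(llcal_m1, k1, n_cal))
    else:
        raise ParameterError(f"unknown convention {convention!r}")
    log_k2 = llval_m1 - llval_m2
    return log_k1, log_k2, log_k1 + log_k2


@dataclass
class CVResult:
    """Fold-averaged goodness-of-fit table and composite Bayes factors."""

    table: pd.DataFrame
    folds: int
    seed: int
    fold_assignments: np.ndarray
    reference_label: str

    def summary(self) -> str:
        lines = [
            f"{self.folds}-fold cross-validation "
            f"(reference: {self.reference_label}, seed {self.seed})",
            self.table.to_string(
                index=False, float_format=lambda v: f"{v:.2f}"
            ),
        ]
        return "\n".join(lines)


def cv_compare(
    sample: pd.DataFrame,
    specs: list[ModelSpec],
    folds: int = 4,
    seed: int = 0,
    reference: ModelSpec | None = None,
    single_split: bool = False,
) -> CVResult:
    """Cross-validate a list of specs against a fully heterogeneous reference.

    ``sample`` is an ``extract_adjustments`` frame; each spec's own
    conditioning is applied before partitioning.  ``single_split`` evaluates
    only the first fold (one 75/25 split) instead of rotating.

    The headline ``log_k`` column uses the "bic" orientation (positive
    favors the reference); ``log_k_printed`` carries the verbatim form.
    """
    if reference is None:
        reference = ModelSpec("subject", "subject", "subject", specs[0].conditioning)
    if not any(
        (s.alpha, s.beta, s.sigma) == (reference.alpha, reference.beta, reference.sigma)
        for s in specs
    ):
        specs = [reference, *specs]

    cond = sample[sample["adjusted"]] if reference.conditioning == "adjust" else sample
    y = cond["y"].to_numpy()
    x = cond["x"].to_numpy()
    subj = cond["subject_id"].to_numpy()
    assign = kfold_partition(subj, folds=folds, seed=seed)
    fold_ids = [0] if single_split else list(range(folds))

    per_fold = {s.label: [] for s in specs}
    for f in fold_ids:
        val = assign == f
        cal = ~val
        n_cal = int(cal.sum())
        fits: dict[str, LLOResults] = {}
        for spec in specs:
            res = LinearLogOddsModel(y[cal], x[cal], subj[cal], spec).fit()
            llval = res.loglik(y[val], x[val], subj[val])
            fits[spec.label] = (res, llval, n_cal)
        ref_res, ref_llval, _ = fits[reference.label]
        for spec in specs:
            res, llval, _ = fits[spec.label]
            _, _, log_k_bic = composite_log_bayes_factor(
                ref_res.llf, res.llf, ref_llval, llval,
                ref_res.k, res.k, n_cal, convention="bic",
            )
            _, _, log_k_printed = composite_log_bayes_factor(
                ref_res.llf, res.llf, ref_llval, llval,
                ref_res.k, res.k, n_cal, convention="printed",
            )
            per_fold[spec.label].append(
                {
                    "bic_calibration": res.bic,
                    "bic_validation": -2.0 * llval,
                    "log_k": log_k_bic,
                    "log_k_printed": log_k_printed,
                }
            )
    rows = []
    for spec in specs:
        chunk = pd.DataFrame(per_fold[spec.label])
        rows.append(
            {
                "model": spec.label,
                "k": spec.n_free(len(pd.unique(subj))),
                **chunk.mean().to_dict(),
            }
        )
    return CVResult(
        table=pd.DataFrame(rows),
        folds=folds,
        seed=seed,
        fold_assignments=assign,
        reference_label=reference.label,
    )
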