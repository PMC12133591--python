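"""Parameter containers for the three pipeline stages.

All tunables are plain dataclasses with documented defaults; ``validate()``
raises :class:`~surfacer.errors.ParameterError` naming the offending field,
so a bad YAML entry fails loudly before any data is touched.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .errors import ParameterError

#: Lymphoid tissues used by the specificity filter: the tissues in which a
#: safe hematological CAR target is allowed (and expected) to be expressed.
DEFAULT_LYMPHOID_TISSUES: tuple[str, ...] = (
    "bone marrow",
    "spleen",
    "blood",
    "lymph node",
    "thymus",
    "tonsil",
)

#: Cell types whose expression disqualifies a candidate (on-target/off-tumor
#: risk): T-cell subsets and granulocytes, plus hematopoietic stem cells.
DEFAULT_EXCLUDED_CELLTYPES: tuple[str, ...] = (
    "CD4 T cell",
    "CD8 T cell",
    "regulatory T cell",
    "neutrophil",
    "basophil",
    "eosinophil",
    "HSC",
)

VALID_MODES = ("intensity", "peptide", "either")


def _check(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ParameterError(f"{fieldname}: {msg}")


@dataclass
class CohortConfig:
    """Configuration of one synthetic PDX cohort.

    Replicate counts follow the study design (4 biotinylated runs, 2
    non-biotinylated controls per PDX). Intensity parameters are on the
    log2 scale of LFQ intensities.
    """

    n_pdx: int = 6
    n_proteins: int = 2000
    n_true_targets: int = 20
    #: enriched surface decoys planted per non-lymphoid-restricted archetype
    #: (t_cell, myeloid, single_nonlymphoid, ubiquitous); only planted when
    #: n_true_targets > 0 so that a zero-target cohort is a genuine null.
    n_decoys_per_archetype: int = 5
    n_biot_reps: int = 4
    n_nb_reps: int = 2
    enrichment_log2fc: float = 3.0
    baseline_mu: float = 25.0
    baseline_sigma: float = 2.0
    noise_sigma: float = 0.5
    missing_censor_quantile: float = 0.2
    detect_dropout_rate: float = 0.15
    seed: int = 0

    def validate(self) -> "CohortConfig":
        for f in ("n_pdx", "n_proteins", "n_true_targets",
                  "n_decoys_per_archetype", "n_biot_reps", "n_nb_reps"):
            _check(int(getattr(self, f)) >= 0, f, "must be a non-negative count")
        _check(self.n_true_targets <= self.n_proteins,
               "n_true_targets", "cannot exceed n_proteins")
        planted = self.n_true_targets
        if planted > 0:
            planted += 4 * self.n_decoys_per_archetype
        _check(planted <= self.n_proteins,
               "n_decoys_per_archetype", "targets plus decoys exceed n_proteins")
        _check(self.n_biot_reps >= 1, "n_biot_reps", "need at least one biot run")
        _check(self.n_nb_reps >= 1, "n_nb_reps", "need at least one nb run")
        _check(0.0 <= self.missing_censor_quantile <= 1.0,
               "missing_censor_quantile", "must lie in [0, 1]")
        _check(0.0 <= self.detect_dropout_rate <= 1.0,
               "detect_dropout_rate", "must lie in [0, 1]")
        _check(self.baseline_sigma >= 0, "baseline_sigma", "must be >= 0")
        _check(self.noise_sigma >= 0, "noise_sigma", "must be >= 0")
        return self


@dataclass
class CallParams:
    """Parameters of the per-PDX surface-detection call.

    The statistical defaults (s0, imputation width/downshift, permutation
    count) are the Perseus conventions for label-free enrichment testing.
    ``mode`` selects the evidence used for the ``detected`` flag:
    the intensity rule (q/effect-size thresholds), the specific-peptide
    count rule, or their disjunction.
    """

    s0: float = 0.1
    n_perm: int = 250
    q_max: float = 0.05
    log2fc_min: float = 1.0
    min_biot_quantified: int = 3
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    min_pep_biot: int = 2
    min_pep_reps: int = 3
    max_pep_nb: int = 1
    mode: str = "either"
    seed: int = 0

    def validate(self, n_biot_runs: int | None = None) -> "CallParams":
        _check(self.s0 >= 0, "s0", "must be >= 0")
        _check(self.n_perm >= 1, "n_perm", "must be >= 1")
        _check(0.0 <= self.q_max <= 1.0, "q_max", "must lie in [0, 1]")
        _check(self.impute_width > 0, "impute_width", "must be > 0")
        _check(self.mode in VALID_MODES, "mode",
               f"must be one of {VALID_MODES}")
        _check(self.min_biot_quantified >= 0, "min_biot_quantified",
               "must be a non-negative count")
        if n_biot_runs is not None:
            _check(self.min_biot_quantified <= n_biot_runs,
                   "min_biot_quantified",
                   f"cannot exceed the number of biot runs ({n_biot_runs})")
        for f in ("min_pep_biot", "min_pep_reps", "max_pep_nb"):
            _check(int(getattr(self, f)) >= 0, f, "must be a non-negative count")
        return self


@dataclass
class TriageParams:
    """Thresholds of the candidate triage cascade.

    The four specificity conjuncts (tau, lymphoid argmax, lymphoid fold,
    absolute non-lymphoid cap) can be toggled individually.
    """

    min_pdx: int = 3
    tau_min: float = 0.8
    lymphoid_fold_min: float = 4.0
    nonlymphoid_abs_max: float = 10.0
    exclude_frac_max: float = 0.10
    epsilon: float = 1e-6
    use_tau: bool = True
    use_lymphoid_argmax: bool = True
    use_lymphoid_fold: bool = True
    use_nonlymphoid_abs: bool = True
    lymphoid_tissues: tuple[str, ...] = DEFAULT_LYMPHOID_TISSUES
    excluded_celltypes: tuple[str, ...] = DEFAULT_EXCLUDED_CELLTYPES

    def validate(self, n_pdx: int | None = None) -> "TriageParams":
        _check(self.min_pdx >= 1, "min_pdx", "must be >= 1")
        if n_pdx is not None:
            _check(self.min_pdx <= n_pdx, "min_pdx",
                   f"cannot exceed the number of PDX samples ({n_pdx})")
        _check(0.0 <= self.tau_min <= 1.0, "tau_min", "must lie in [0, 1]")
        _check(self.lymphoid_fold_min >= 1.0, "lymphoid_fold_min", "must be >= 1")
        _check(self.nonlymphoid_abs_max >= 0, "nonlymphoid_abs_max", "must be >= 0")
        _check(0.0 <= self.exclude_frac_max <= 1.0,
               "exclude_frac_max", "must lie in [0, 1]")
        _check(self.epsilon > 0, "epsilon", "must be > 0")
        _check(len(self.lymphoid_tissues) > 0,
               "lymphoid_tissues", "must not be empty")
        return self


def _from_dict(cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ParameterError(
            f"{cls.__name__}: unknown field(s) {sorted(unknown)}")
    kwargs = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(f.default, tuple):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


def cohort_config_from_dict(data: dict) -> CohortConfig:
    return _from_dict(CohortConfig, data).validate()


def call_params_from_dict(data: dict) -> CallParams:
    return _from_dict(CallParams, data).validate()


def triage_params_from_dict(data: dict) -> TriageParams:
    return _from_dict(TriageParams, data).validate()
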