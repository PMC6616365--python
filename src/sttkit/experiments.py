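"""End-to-end seeded screening experiments on synthetic cohorts.

One replicate mirrors the original study design: simulate a training
cohort of 10 patients + 20 controls and a validation cohort of 15 patients
+ 18 controls, extract the four dexterity variables from every trace,
train the 4-3-2 scoring network on the training cohort, and score the
validation cohort.  All randomness derives from a single replicate seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ann import MLPParams, TrainConfig, stt_score, train_mlp
from .features import FeatureVector, cycle_features, extract_features
from .simulate import CohortSpec, default_profiles, simulate_cohort
from .task_geometry import TaskFigure

__all__ = ["ScreeningReplicate", "screening_replicate"]


@dataclass(frozen=True)
class ScreeningReplicate:
    """Everything one simulated train/validate round produced."""

    params: MLPParams
    train_features: list[FeatureVector]
    train_labels: np.ndarray
    val_features: list[FeatureVector]
    val_labels: np.ndarray
    val_scores: np.ndarray


def screening_replicate(
    seed: int,
    figure: TaskFigure | None = None,
    n_train: tuple[int, int] = (10, 20),
    n_val: tuple[int, int] = (15, 18),
    mode: str = "nearest",
    train_config: TrainConfig | None = None,
) -> ScreeningReplicate:
    """Simulate, train and score one full replicate under the default profiles.

    Cohort sizes are (patients, controls); training and validation cohorts
    and the weight initialization get disjoint seeds derived from ``seed``.
    """
    figure = figure or TaskFigure()
    control, patient = default_profiles()
    ss = np.random.SeedSequence(seed).generate_state(3) % 2**31
    cohorts = {}
    for key, (n_pat, n_ctl), s in (("train", n_train, ss[0]), ("val", n_val, ss[1])):
        traces, manifest = simulate_cohort(
            figure, CohortSpec(n_pat, n_ctl, patient, control, seed=int(s))
        )
        fvs = [extract_features(t, figure, mode) for t in traces]
        cohorts[key] = (traces, fvs, manifest["group"].to_numpy())
    cfg = train_config if train_config is not None else TrainConfig(seed=int(ss[2]))
    params = train_mlp(cohorts["train"][1], list(cohorts["train"][2]), cfg)
    scores = np.array([stt_score(params, fv).value for fv in cohorts["val"][1]])
    return ScreeningReplicate(
        params=params,
        train_features=cohorts["train"][1],
        train_labels=cohorts["train"][2],
        val_features=cohorts["val"][1],
        val_labels=cohorts["val"][2],
        val_scores=scores,
    )


def cycle_score_matrix(
    seed: int,
    params: MLPParams,
    figure: TaskFigure | None = None,
    n_val: tuple[int, int] = (15, 18),
    mode: str = "nearest",
):
    """Per-cycle score matrix (subjects x 3 cycles) for a fresh validation cohort."""
    figure = figure or TaskFigure()
    control, patient = default_profiles()
    s = int(np.random.SeedSequence(seed).generate_state(2)[1] % 2**31)
    traces, manifest = simulate_cohort(
        figure, CohortSpec(n_val[0], n_val[1], patient, control, seed=s)
    )
    matrix = np.array(
        [[stt_score(params, fv).value for fv in cycle_features(t, figure, mode)] for t in traces]
    )
    return matrix, manifest["group"].to_numpy()
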