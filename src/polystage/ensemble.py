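"""Noise-weighted integration of the five staging models and expert rules.

Each epoch's five probability vectors are combined as a weighted average,
with the weight of any model whose channel group is flagged as noisy reset
to zero for that epoch.  The integrated prediction is then post-processed by
the REM-continuity expert rule: rapid eye movements are absent in tonic REM,
so epochs inside a REM period are often mis-scored as N1/N2 by the models;
looking ahead up to eight epochs and forcing such epochs to R restores the
continuity of the REM bout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Hypnogram, PSGRecord, STAGES, STAGE_INDEX
from .network import StagingModel, default_groups, predict_proba, select_group_channels
from .noise import NoiseConfig, NoiseMask, detect_noise
from .preprocess import PreprocessConfig, downsample_record, splice_epochs


@dataclass
class EnsembleWeights:
    """Unnormalized non-negative model weights; normalized at use."""

    w: np.ndarray = field(default_factory=lambda: np.ones(5))

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        if np.any(self.w < 0):
            raise ValueError("ensemble weights must be non-negative")
        if not np.any(self.w > 0):
            raise ValueError("at least one ensemble weight must be positive")

    @classmethod
    def uniform(cls, n: int = 5) -> "EnsembleWeights":
        return cls(np.ones(n))

    @classmethod
    def from_validation_accuracy(cls, accs: np.ndarray) -> "EnsembleWeights":
        return cls(np.asarray(accs, dtype=np.float64))


@dataclass
class ExpertRuleConfig:
    lookahead_epochs: int = 8
    mode: str = "gap_fill"          # "gap_fill" | "literal"

    def __post_init__(self) -> None:
        if self.lookahead_epochs < 1:
            raise ValueError("lookahead must be >= 1")
        if self.mode not in ("gap_fill", "literal"):
            raise ValueError("mode must be 'gap_fill' or 'literal'")


def integrate(
    probs: np.ndarray,
    weights: EnsembleWeights | None = None,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Weighted-average probability fusion for one epoch.

    Parameters
    ----------
    probs : (n_models, 5) normalized probability vectors.
    weights : unnormalized model weights (default uniform).
    mask : boolean per-model noise flags; flagged models get weight zero.

    Returns
    -------
    (5,) integrated probability vector, and a low-confidence flag that is
    set when every model was masked (the fusion then falls back to a uniform
    average over all models).
    """
    probs = np.asarray(probs, dtype=np.float64)
    weights = weights or EnsembleWeights.uniform(probs.shape[0])
    w = weights.w.astype(np.float64).copy()
    if w.shape[0] != probs.shape[0]:
        raise ValueError("one weight per model required")
    low_confidence = False
    if mask is not None:
        w[np.asarray(mask, dtype=bool)] = 0.0
    if w.sum() <= 0:
        w = np.ones(probs.shape[0])
        low_confidence = True
    w = w / w.sum()
    out = w @ probs
    return out / out.sum(), low_confidence


def integrate_record(
    probs: np.ndarray,
    weights: EnsembleWeights | None = None,
    mask: NoiseMask | np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized fusion over a record: (n_models, n_epochs, 5) → (n_epochs, 5)."""
    probs = np.asarray(probs, dtype=np.float64)
    n_models, n_epochs, _ = probs.shape
    flags = None
    if mask is not None:
        flags = mask.flags if isinstance(mask, NoiseMask) else np.asarray(mask, bool)
    fused = np.empty((n_epochs, 5))
    low = np.zeros(n_epochs, dtype=bool)
    for e in range(n_epochs):
        fused[e], low[e] = integrate(
            probs[:, e, :],
            weights,
            None if flags is None else flags[e],
        )
    return fused, low


def argmax_stage(probs: np.ndarray) -> np.ndarray:
    """Most probable stage per epoch; ties go to the lowest stage index."""
    return np.asarray(probs).argmax(axis=-1)     # argmax is first-max: W<N1<N2<N3<R


def apply_expert_rules(
    stages: list[str] | np.ndarray,
    cfg: ExpertRuleConfig | None = None,
) -> list[str]:
    """REM-continuity post-processing on a predicted label sequence.

    ``literal`` mode applies the written procedure in one simultaneous pass:
    any epoch whose next ``lookahead_epochs`` epochs (in the input) contain
    an R prediction is forced to R.  ``gap_fill`` (default) only converts
    non-R runs of length ≤ lookahead lying strictly between two R epochs —
    the reading consistent with the rule's stated purpose of preserving REM
    continuity, since the literal pass would also convert long pre-REM wake
    runs.  The rule only ever changes labels *to* R.  gap_fill is idempotent;
    literal is not in general (newly created R epochs would recruit more
    epochs on a second pass).
    """
    cfg = cfg or ExpertRuleConfig()
    labels = [str(s) for s in stages]
    for l in labels:
        if l not in STAGE_INDEX:
            raise ValueError(f"label {l!r} outside the 5-stage alphabet")
    n = len(labels)
    is_r = [l == "R" for l in labels]
    out = list(labels)
    if cfg.mode == "literal":
        for i in range(n):
            if any(is_r[i + 1 : i + 1 + cfg.lookahead_epochs]):
                out[i] = "R"
        return out
    # gap_fill: maximal non-R runs strictly between two R epochs, len <= lookahead
    i = 0
    while i < n:
        if not is_r[i]:
            j = i
            while j < n and not is_r[j]:
                j += 1
            run_len = j - i
            bounded = i > 0 and is_r[i - 1] and j < n and is_r[j]
            if bounded and run_len <= cfg.lookahead_epochs:
                for k in range(i, j):
                    out[k] = "R"
            i = j
        else:
            i += 1
    return out


@dataclass
class ScoredRecord:
    """Final pipeline output for one record."""

    hypnogram: Hypnogram                  # post-expert-rule labels
    probabilities: np.ndarray             # (n_epochs, 5) integrated
    pre_rule_labels: list[str]            # integrated argmax before expert rules
    per_model_probabilities: np.ndarray   # (n_models, n_epochs, 5)
    noise_mask: NoiseMask
    low_confidence: np.ndarray            # (n_epochs,) all-models-masked flag

    def to_frame(self):
        """Per-epoch CSV-ready table: probabilities, top-1/top-2, masked groups."""
        import pandas as pd

        order = np.argsort(-self.probabilities, axis=1, kind="stable")
        rows = {
            "epoch": np.arange(len(self.hypnogram)),
            **{f"p_{s}": self.probabilities[:, i] for i, s in enumerate(STAGES)},
            "top1": [STAGES[i] for i in order[:, 0]],
            "top2": [STAGES[i] for i in order[:, 1]],
            "stage": self.hypnogram.labels,
            "masked_groups": [
                ";".join(str(g) for g in np.flatnonzero(self.noise_mask.flags[e]))
                for e in range(len(self.hypnogram))
            ],
        }
        return pd.DataFrame(rows)


def score_record(
    record: PSGRecord,
    models: list[StagingModel],
    groups: list[list[str]] | None = None,
    weights: EnsembleWeights | None = None,
    preprocess_cfg: PreprocessConfig | None = None,
    noise_cfg: NoiseConfig | None = None,
    rule_cfg: ExpertRuleConfig | None = None,
    use_noise_detection: bool = True,
    use_expert_rules: bool = True,
    silence_all_channel_group: bool = True,
) -> ScoredRecord:
    """Full scoring pipeline for one source-rate record.

    preprocess → per-group predict → noise mask → weighted integration →
    argmax → REM-continuity rule.  Deterministic given the trained models.
    Ablation switches: ``use_noise_detection`` and ``use_expert_rules``
    disable the respective stage; ``silence_all_channel_group=False`` keeps
    the all-channel model's weight even when one of its members is noisy.
    """
    groups = groups or default_groups()
    if len(models) != len(groups):
        raise ValueError("one trained model per channel group required")
    pcfg = preprocess_cfg or PreprocessConfig()

    rec_ds = downsample_record(record, pcfg)
    windows = splice_epochs(rec_ds, None, pcfg)
    X = np.stack([w.data for w in windows]).astype(np.float32)
    per_model = np.stack([
        predict_proba(m, select_group_channels(X, g))
        for m, g in zip(models, groups)
    ])

    n_epochs = len(windows)
    if use_noise_detection:
        mask_groups = list(groups)
        if not silence_all_channel_group:
            mask_groups = [g if len(g) == 1 else [] for g in groups]
        mask = detect_noise(record, mask_groups, noise_cfg or NoiseConfig())
        if mask.n_epochs != n_epochs:
            mask = NoiseMask(mask.flags[:n_epochs], mask.reasons)
    else:
        mask = NoiseMask(np.zeros((n_epochs, len(groups)), dtype=bool))

    fused, low = integrate_record(per_model, weights, mask)
    pre_rule = [STAGES[i] for i in argmax_stage(fused)]
    final = apply_expert_rules(pre_rule, rule_cfg) if use_expert_rules else list(pre_rule)
    return ScoredRecord(
        hypnogram=Hypnogram(final, pcfg.epoch_s),
        probabilities=fused,
        pre_rule_labels=pre_rule,
        per_model_probabilities=per_model,
        noise_mask=mask,
        low_confidence=low,
    )
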