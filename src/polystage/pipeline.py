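"""End-to-end orchestration: config, dataset assembly, training, ablations.

A dataset is a list of records with hypnograms and metadata, split into
train/validation/test **by recording** (never by epoch — epochs of one
subject must not leak across splits).  ``run_experiment`` trains the five
group models once and evaluates any requested ablation variants on the
shared test split:

* ``full``      — splice + noise detection + expert rules (the proposed model)
* ``no_expert`` — expert rules off
* ``no_noise``  — noise detection off
* ``no_splice`` — 1-epoch windows (context_epochs=1); needs its own model set
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ensemble import EnsembleWeights, ExpertRuleConfig, score_record
from .evaluate import EvaluationReport, evaluate
from .io import (Hypnogram, PSGRecord, RecordMetadata, ROLES, read_hypnogram,
                 read_psg)
from .network import (NetworkSpec, StagingModel, TrainConfig, build_network,
                      default_groups, default_network_spec, select_group_channels,
                      train_model)
from .noise import NoiseConfig
from .preprocess import (PreprocessConfig, downsample_record, splice_epochs,
                         windows_to_arrays)
from .synth import (FalloffEvent, scenario_preset, generate_record,
                    inject_falloff as ps_inject_falloff)

log = logging.getLogger("polystage")

VARIANTS = ("full", "no_expert", "no_noise", "no_splice")


class LeakageError(ValueError):
    """A subject appears in more than one split."""


@dataclass
class DatasetItem:
    record: PSGRecord
    hypnogram: Hypnogram
    metadata: RecordMetadata
    split: str                      # train | val | test

    def __post_init__(self):
        if self.split not in ("train", "val", "test"):
            raise ValueError(f"unknown split {self.split!r}")


@dataclass
class PipelineConfig:
    """Every knob of the workflow, serializable to YAML."""

    montage_map: dict[str, str] = field(
        default_factory=lambda: {r.replace("_", " "): r for r in ROLES})
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    network: NetworkSpec = field(default_factory=default_network_spec)
    train: TrainConfig = field(default_factory=TrainConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    rules: ExpertRuleConfig = field(default_factory=ExpertRuleConfig)
    weight_policy: str = "uniform"        # "uniform" | "validation_accuracy"
    seed: int = 0

    def __post_init__(self):
        if self.weight_policy not in ("uniform", "validation_accuracy"):
            raise ValueError("weight_policy must be uniform|validation_accuracy")
        missing = [r for r in ROLES if r not in self.montage_map.values()]
        if missing:
            raise ValueError(f"montage map does not assign roles {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw: dict = {}
        if "montage_map" in raw:
            kw["montage_map"] = dict(raw["montage_map"])
        for key, klass in (("preprocess", PreprocessConfig), ("train", TrainConfig),
                           ("noise", NoiseConfig), ("rules", ExpertRuleConfig)):
            if key in raw:
                kw[key] = klass(**raw[key])
        if "network" in raw:
            from .network import BlockSpec
            kw["network"] = NetworkSpec(
                blocks=tuple(BlockSpec(**b) for b in raw["network"]["blocks"]))
        for key in ("weight_policy", "seed"):
            if key in raw:
                kw[key] = raw[key]
        return cls(**kw)


# ---------------------------------------------------------------------------
# Synthetic dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudyConfig:
    """A scaled-down synthetic study shaped like a clinical OSA population.

    The defaults are the reference desk-scale conditions: 12 overnight
    records of 160 epochs (~80 min each), split 7/2/3 by recording.
    """

    n_records: int = 12
    epochs_per_record: int = 160
    scenario: str = "severe_osa"
    train_fraction: float = 0.6
    val_fraction: float = 0.15
    arousal_rate_mean: float = 8.0        # Poisson mean arousals per record
    seed: int = 0


def make_synthetic_dataset(cfg: SyntheticStudyConfig) -> list[DatasetItem]:
    """Generate a population of seeded synthetic records with AHI metadata.

    AHI is drawn per record across the four severity classes (severe
    weighted most, mirroring a sleep-clinic case mix) and the arousal count
    grows with AHI, so the severity stratification and arousal analyses have
    signal to find.
    """
    rng = np.random.default_rng((cfg.seed, 5))
    items: list[DatasetItem] = []
    n_train = max(1, int(round(cfg.train_fraction * cfg.n_records)))
    n_val = max(1, int(round(cfg.val_fraction * cfg.n_records)))
    for r in range(cfg.n_records):
        sev = rng.choice(4, p=[0.15, 0.15, 0.20, 0.50])
        ahi = float([rng.uniform(0.5, 4.9), rng.uniform(5, 14.9),
                     rng.uniform(15, 29.9), rng.uniform(30, 90)][sev])
        arousals = int(rng.poisson(cfg.arousal_rate_mean * (0.5 + 0.5 * sev)))
        scenario = scenario_preset(
            cfg.scenario, n_epochs=cfg.epochs_per_record,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        # an arousal needs a sleep epoch to land on
        from .synth import simulate_hypnogram
        n_sleep = sum(1 for l in simulate_hypnogram(scenario).labels if l != "W")
        arousals = min(arousals, cfg.epochs_per_record // 4, n_sleep)
        scenario.arousal_count = arousals
        record, hyp, _ = generate_record(scenario)
        split = "train" if r < n_train else ("val" if r < n_train + n_val else "test")
        items.append(DatasetItem(
            record, hyp,
            RecordMetadata(subject_id=f"synth-{r:03d}", ahi=ahi,
                           arousal_count=arousals),
            split,
        ))
    return items


def load_manifest_dataset(
    manifest_path: str | Path, montage_map: dict[str, str]
) -> list[DatasetItem]:
    """Read a CSV manifest: record_path, hypnogram_path, split, subject_id, ahi, arousal_count."""
    man = pd.read_csv(manifest_path)
    required = {"record_path", "hypnogram_path", "split", "subject_id"}
    if not required.issubset(man.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    # validate split discipline over the whole manifest before any file I/O
    seen: dict[str, str] = {}
    for _, row in man.iterrows():
        sid = str(row["subject_id"])
        if sid in seen and seen[sid] != row["split"]:
            raise LeakageError(f"subject {sid} appears in splits "
                               f"{seen[sid]!r} and {row['split']!r}")
        seen[sid] = row["split"]
    items = []
    base = Path(manifest_path).parent
    for _, row in man.iterrows():
        sid = str(row["subject_id"])
        rec = read_psg(base / str(row["record_path"]), montage_map)
        hyp = read_hypnogram(base / str(row["hypnogram_path"]))
        meta = RecordMetadata(
            subject_id=sid,
            ahi=float(row["ahi"]) if "ahi" in man.columns and pd.notna(row.get("ahi")) else None,
            arousal_count=int(row["arousal_count"])
            if "arousal_count" in man.columns and pd.notna(row.get("arousal_count")) else None,
        )
        items.append(DatasetItem(rec, hyp, meta, str(row["split"])))
    return items


def check_split_discipline(items: list[DatasetItem]) -> None:
    seen: dict[str, str] = {}
    for it in items:
        sid = it.metadata.subject_id
        if sid in seen and seen[sid] != it.split:
            raise LeakageError(f"subject {sid} appears in splits "
                               f"{seen[sid]!r} and {it.split!r}")
        seen[sid] = it.split


# ---------------------------------------------------------------------------
# Training and scoring over a dataset
# ---------------------------------------------------------------------------

def _dataset_windows(items, pcfg: PreprocessConfig, split: str):
    Xs, ys = [], []
    for it in items:
        if it.split != split:
            continue
        rec = downsample_record(it.record, pcfg)
        wins = splice_epochs(rec, it.hypnogram, pcfg)
        X, y = windows_to_arrays(wins)
        Xs.append(X)
        ys.append(y)
    if not Xs:
        return None, None
    return np.concatenate(Xs), np.concatenate(ys)


@dataclass
class TrainedEnsemble:
    models: list[StagingModel]
    groups: list[list[str]]
    weights: EnsembleWeights
    histories: list[dict]
    config: PipelineConfig


def train_group_models(
    items: list[DatasetItem],
    config: PipelineConfig,
) -> TrainedEnsemble:
    """Train the five channel-group networks on the train split."""
    check_split_discipline(items)
    pcfg = config.preprocess
    X_tr, y_tr = _dataset_windows(items, pcfg, "train")
    if X_tr is None or len({it.metadata.subject_id for it in items
                            if it.split == "train"}) < 2:
        raise ValueError("need at least two training recordings")
    X_val, y_val = _dataset_windows(items, pcfg, "val")

    groups = default_groups()
    models, histories, val_accs = [], [], []
    for gi, roles in enumerate(groups):
        log.info("training group %d (%s): %d windows", gi + 1, "+".join(roles), len(X_tr))
        model = build_network(config.network, len(roles), pcfg.window_samples,
                              seed=config.train.seed + gi)
        hist = train_model(
            model,
            select_group_channels(X_tr, roles), y_tr,
            replace(config.train, seed=config.train.seed + gi),
            select_group_channels(X_val, roles) if X_val is not None else None,
            y_val,
        )
        models.append(model)
        histories.append(hist)
        va = [a for a in hist["val_acc"] if np.isfinite(a)]
        val_accs.append(max(va) if va else 1.0)

    if config.weight_policy == "validation_accuracy":
        weights = EnsembleWeights.from_validation_accuracy(np.array(val_accs))
    else:
        weights = EnsembleWeights.uniform(len(groups))
    return TrainedEnsemble(models, groups, weights, histories, config)


def score_dataset(
    ensemble: TrainedEnsemble,
    items: list[DatasetItem],
    split: str = "test",
    use_noise_detection: bool = True,
    use_expert_rules: bool = True,
) -> EvaluationReport:
    """Score every record in a split and evaluate against the expert labels."""
    cfg = ensemble.config
    true_all, pred_all, probs_all, ahi_all = [], [], [], []
    for it in items:
        if it.split != split:
            continue
        scored = score_record(
            it.record, ensemble.models, ensemble.groups, ensemble.weights,
            cfg.preprocess, cfg.noise, cfg.rules,
            use_noise_detection=use_noise_detection,
            use_expert_rules=use_expert_rules,
        )
        true_all.extend(it.hypnogram.labels)
        pred_all.extend(scored.hypnogram.labels)
        probs_all.append(scored.probabilities)
        ahi = it.metadata.ahi if it.metadata.ahi is not None else np.nan
        ahi_all.extend([ahi] * len(it.hypnogram))
    probs = np.concatenate(probs_all)
    ahi_arr = np.asarray(ahi_all)
    return evaluate(true_all, pred_all, probs,
                    ahi_arr if np.isfinite(ahi_arr).all() else None)


def corrupt_test_split(
    items: list[DatasetItem],
    fraction: float = 0.10,
    role: str = "EEG_C3A2",
    seed: int = 0,
) -> list[DatasetItem]:
    """Inject electrode falloff on one channel over ``fraction`` of each test
    record's epochs (uniformly chosen, mixed modes); train/val untouched."""
    rng = np.random.default_rng((seed, 99))
    out = []
    for it in items:
        if it.split != "test":
            out.append(it)
            continue
        n_ep = len(it.hypnogram)
        rec = it.record
        starts = rng.choice(n_ep, size=int(fraction * n_ep), replace=False)
        for s in starts:
            mode = ("flatline", "saturation", "hf_noise")[int(rng.integers(3))]
            rec = ps_inject_falloff(rec, FalloffEvent(role, int(s), 1, mode))
        out.append(DatasetItem(rec, it.hypnogram, it.metadata, it.split))
    return out


def arousal_sensitivity(
    ensemble: "TrainedEnsemble",
    counts: tuple[int, ...] = (0, 20, 40),
    n_seeds: int = 5,
    n_epochs: int = 120,
    scenario: str = "severe_osa",
    seed: int = 0,
) -> dict[int, list[float]]:
    """Top-2 − top-1 accuracy gap versus injected arousal load.

    For each seed, one fresh record is generated per arousal count and
    scored with the trained ensemble; the returned gaps quantify how much
    scoring ambiguity the arousals introduce.
    """
    cfg = ensemble.config
    gaps: dict[int, list[float]] = {c: [] for c in counts}
    for s in range(n_seeds):
        for count in counts:
            sc = scenario_preset(scenario, n_epochs=n_epochs,
                                 seed=10_000 + seed + 17 * s)
            sc.arousal_count = count
            rec, hyp, _ = generate_record(sc)
            scored = score_record(rec, ensemble.models, ensemble.groups,
                                  ensemble.weights, cfg.preprocess, cfg.noise,
                                  cfg.rules)
            from .evaluate import topk_accuracy
            t1 = topk_accuracy(hyp, scored.probabilities, 1)
            t2 = topk_accuracy(hyp, scored.probabilities, 2)
            gaps[count].append(t2 - t1)
    return gaps


def run_experiment(
    items: list[DatasetItem],
    config: PipelineConfig | None = None,
    variants: tuple[str, ...] = ("full", "no_expert", "no_noise"),
) -> dict[str, EvaluationReport]:
    """Train once, then evaluate the requested ablation variants on the test split.

    ``no_splice`` trains a second model set on 1-epoch windows; the other
    variants share the full model set and differ only in post-processing.
    """
    config = config or PipelineConfig()
    for v in variants:
        if v not in VARIANTS:
            raise ValueError(f"unknown variant {v!r}; choose from {VARIANTS}")
    ensemble = train_group_models(items, config)
    reports: dict[str, EvaluationReport] = {}
    for v in variants:
        if v == "no_splice":
            cfg1 = replace(config,
                           preprocess=replace(config.preprocess, context_epochs=1))
            ens1 = train_group_models(items, cfg1)
            reports[v] = score_dataset(ens1, items)
        else:
            reports[v] = score_dataset(
                ensemble, items,
                use_noise_detection=(v != "no_noise"),
                use_expert_rules=(v != "no_expert"),
            )
    return reports
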