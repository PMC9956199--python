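"""End-to-end workflow: cohort -> encrypted store -> WOA-seeded CCRBM -> report.

The whale optimizer searches the space of *initial* CCRBM parameters
(filters, hidden biases, visible bias, flattened to a vector in [-1, 1]^D).
Each candidate is unflattened, briefly trained with centered CD, given a
logistic readout, and scored by negative validation accuracy (a
reconstruction-error fitness is available as a config option).  The best
candidate then receives the full training budget, and the final model is
evaluated on the held-out test split.

Every stochastic stage draws its seed deterministically from the master seed
(via ``numpy.random.SeedSequence`` spawning in a fixed order), so a run is
reproducible end to end: same master seed, same cohort, same keys, same
model bytes, same metrics.  The encrypted and plaintext storage paths yield
byte-identical models because features live on the fixed-point grid the
encoder uses, making encrypt -> decrypt the identity.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import ccrbm, crypto, evaluation, woa
from .synth import (
    PatientRecord,
    SyntheticConfig,
    cohort_matrix,
    generate_cohort,
    split_cohort,
    write_cohort,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineError",
    "PipelineConfig",
    "RunArtifacts",
    "derive_seeds",
    "whale_to_params",
    "params_to_whale",
    "make_fitness",
    "train_from_position",
    "run_ccrbm_wo",
    "run_full_pipeline",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the full run, with one master seed.

    Defaults: 5 input features, 1 output unit, learning rate 0.1, whale
    population 20 with 100 iterations, 80/20 train/test split.  The CCRBM
    filter bank defaults to 3 width-4 filters with pool block 2 (one pooled
    feature per filter over the length-2 detection layer), a deliberately
    lean representation in which the quality of the initial filters — what
    the whale optimizer selects — visibly matters.
    """

    n_records: int = 2000
    n_features: int = 5
    class_balance: float = 0.5
    effect_size: float = 2.0
    noise_sd: float = 1.0
    n_informative: int = 2

    scheme: str = crypto.ADDITIVE
    key_bits: int = 512
    precision: int = 6
    encrypt: bool = True

    n_filters: int = 3
    filter_width: int = 4
    pool_block: int = 2
    learning_rate: float = 0.1
    cd_k: int = 1
    batch_size: int = 64
    ema_rate: float = 0.01

    population_size: int = 20
    iterations: int = 100
    spiral_constant: float = 1.0

    train_fraction: float = 0.8
    validation_fraction: float = 0.2
    e_inner: int = 5
    e_final: int = 50
    fitness_metric: str = "accuracy"  # or "reconstruction"
    adversary_dictionary_size: int = 100

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise PipelineError("train_fraction must lie in (0, 1)")
        if self.fitness_metric not in ("accuracy", "reconstruction"):
            raise PipelineError(f"unknown fitness metric {self.fitness_metric!r}")

    @property
    def synthetic(self) -> SyntheticConfig:
        return SyntheticConfig(
            n_records=self.n_records,
            n_features=self.n_features,
            class_balance=self.class_balance,
            effect_size=self.effect_size,
            noise_sd=self.noise_sd,
            n_informative=self.n_informative,
            seed=derive_seeds(self.seed)["cohort"],
        )

    @property
    def structure(self) -> ccrbm.CCRBMStructure:
        return ccrbm.CCRBMStructure(
            visible_length=self.n_features,
            n_filters=self.n_filters,
            filter_width=self.filter_width,
            pool_block=self.pool_block,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


_STAGES = (
    "cohort", "keys", "encrypt", "split", "woa_init", "fitness", "final_train",
    "adversary",
)


def derive_seeds(master_seed: int) -> dict:
    """Deterministically derive one sub-2^31 seed per stochastic stage."""
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


# --------------------------------------------------------------------------
# whale <-> parameter mapping


def whale_to_params(
    position: np.ndarray,
    structure: ccrbm.CCRBMStructure,
    learning_rate: float = 0.1,
) -> ccrbm.CCRBMParameters:
    """Unflatten an optimizer position into CCRBM parameters.

    Order: filters row-major, then per-filter hidden biases, then the visible
    bias.  Centering offsets are initialized from the biases
    (alpha = sigmoid(bias)).
    """
    position = np.asarray(position, dtype=float)
    if position.shape != (structure.n_flat_params,):
        raise PipelineError(
            f"position length {position.shape} != expected ({structure.n_flat_params},)"
        )
    l, w = structure.n_filters, structure.filter_width
    filters = position[: l * w].reshape(l, w)
    hidden_bias = position[l * w : l * w + l]
    visible_bias = float(position[-1])
    params = ccrbm.CCRBMParameters(
        filters=filters,
        hidden_bias=hidden_bias,
        visible_bias=visible_bias,
        alpha_h=np.zeros((l, structure.detection_length)),
        alpha_v=np.zeros(structure.visible_length),
        learning_rate=learning_rate,
    )
    return ccrbm.initialize_offsets(params, structure)


def params_to_whale(params: ccrbm.CCRBMParameters) -> np.ndarray:
    """Flatten filters, hidden biases and the visible bias back to a vector."""
    return np.concatenate(
        [params.filters.ravel(), params.hidden_bias, [params.visible_bias]]
    )


# --------------------------------------------------------------------------
# fitness


def train_from_position(
    position: np.ndarray,
    train_x: np.ndarray,
    train_y: np.ndarray,
    config: PipelineConfig,
    epochs: int,
    seed: int,
) -> ccrbm.CCRBMModel:
    """Unflatten, run centered CD for ``epochs`` and fit the logistic readout."""
    structure = config.structure
    params = whale_to_params(position, structure, config.learning_rate)
    rng = np.random.default_rng(seed)
    params, _ = ccrbm.train_ccrbm(
        train_x,
        params,
        structure,
        epochs=epochs,
        rng=rng,
        batch_size=config.batch_size,
        k=config.cd_k,
        ema_rate=config.ema_rate,
    )
    feats = ccrbm.extract_features(train_x, params, structure)
    readout = ccrbm.train_readout(feats, train_y)
    return ccrbm.CCRBMModel(structure=structure, params=params, readout=readout)


def make_fitness(
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    config: PipelineConfig,
    seed: int,
):
    """Fitness of an initial-parameter candidate (minimization convention).

    ``accuracy`` metric: short CD training + readout, then *negative*
    validation accuracy, bounded in [-1, 0].  ``reconstruction`` metric:
    validation mean-field reconstruction error (lower is better).  A
    diverging candidate receives the worst possible fitness with a warning
    instead of killing the optimizer.
    """
    worst = 0.0 if config.fitness_metric == "accuracy" else np.inf

    def fitness(position: np.ndarray) -> float:
        try:
            model = train_from_position(
                position, train_x, train_y, config, config.e_inner, seed
            )
            if config.fitness_metric == "accuracy":
                pred, _ = model.predict_batch(val_x)
                return -float(np.mean(pred == val_y))
            return ccrbm.reconstruction_error(val_x, model.params, model.structure)
        except ccrbm.CCRBMError as exc:
            warnings.warn(f"candidate training diverged ({exc}); worst fitness")
            return worst if np.isfinite(worst) else 1e6

    return fitness


# --------------------------------------------------------------------------
# training entry points


def _stratified_xy_split(
    x: np.ndarray, y: np.ndarray, holdout_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    records = [
        PatientRecord(patient_id=f"I{i:06d}", features=x[i], label=int(y[i]))
        for i in range(len(y))
    ]
    fit, hold = split_cohort(records, 1.0 - holdout_fraction, seed)
    fx, fy = cohort_matrix(fit)
    hx, hy = cohort_matrix(hold)
    return fx, fy, hx, hy


def run_ccrbm_wo(
    train_records: list[PatientRecord],
    config: PipelineConfig,
) -> tuple[ccrbm.CCRBMModel, list[dict]]:
    """WOA-select initial CCRBM parameters, then train fully from the best.

    Splits the training records into an internal fit/validation pair,
    optimizes initial parameters by validation fitness within [-1, 1]^D, and
    continues with the full CD budget (``e_final`` epochs) from the best
    candidate on the whole training split.  Returns the trained model and the
    per-iteration WOA history.
    """
    seeds = derive_seeds(config.seed)
    x, y = cohort_matrix(train_records)
    if len(set(y.tolist())) < 2:
        raise PipelineError("training split must contain both classes")
    fx, fy, vx, vy = _stratified_xy_split(
        x, y, config.validation_fraction, seeds["split"]
    )
    structure = config.structure
    dim = structure.n_flat_params
    woa_config = woa.WOAConfig(
        lower=-np.ones(dim),
        upper=np.ones(dim),
        population_size=config.population_size,
        iterations=config.iterations,
        spiral_constant=config.spiral_constant,
        seed=seeds["woa_init"],
    )
    fitness = make_fitness(fx, fy, vx, vy, config, seeds["fitness"])
    result = woa.optimize(fitness, woa_config)
    model = train_from_position(
        result.best_position, x, y, config, config.e_final, seeds["final_train"]
    )
    return model, result.history


def run_random_init(
    train_records: list[PatientRecord],
    config: PipelineConfig,
) -> ccrbm.CCRBMModel:
    """Ablation baseline: identical training from a random initial position."""
    seeds = derive_seeds(config.seed)
    x, y = cohort_matrix(train_records)
    rng = np.random.default_rng(seeds["woa_init"])
    dim = config.structure.n_flat_params
    position = rng.uniform(-1.0, 1.0, size=dim)
    return train_from_position(
        position, x, y, config, config.e_final, seeds["final_train"]
    )


# --------------------------------------------------------------------------
# full pipeline


@dataclass
class RunArtifacts:
    """Paths of everything a run persists, stamped with config hash and seed."""

    cohort_csv: Path
    key_json: Path
    store_json: Path
    model_json: Path
    woa_history_jsonl: Path
    report_json: Path
    timings_json: Path
    log_jsonl: Path
    config_hash: str
    seed: int


def _log_stage(log_path: Path, stage: str, **payload) -> None:
    entry = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "stage": stage,
        **payload,
    }
    with open(log_path, "a") as fh:
        fh.write(json.dumps(entry) + "\n")


def run_full_pipeline(config: PipelineConfig, outdir) -> RunArtifacts:
    """Synthesize, encrypt, store, decrypt, train, predict and evaluate.

    Writes: cohort CSV, key JSON, ciphertext store JSON, model JSON, WOA
    history (line-delimited JSON), the deterministic evaluation report and a
    separate wall-clock timing file.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.seed)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    art = RunArtifacts(
        cohort_csv=outdir / "cohort.csv",
        key_json=outdir / "keys.json",
        store_json=outdir / "store.json",
        model_json=outdir / "model.json",
        woa_history_jsonl=outdir / "woa_history.jsonl",
        report_json=outdir / "report.json",
        timings_json=outdir / "timings.json",
        log_jsonl=outdir / "run_log.jsonl",
        config_hash=stamp["config_hash"],
        seed=config.seed,
    )
    art.log_jsonl.write_text("")

    def stage(name):
        _log_stage(art.log_jsonl, name)

    try:
        stage("cohort")
        records = generate_cohort(config.synthetic)
        write_cohort(records, art.cohort_csv)
    except Exception as exc:
        raise PipelineError(f"stage 'cohort' failed: {exc}") from exc

    timings: dict[str, float] = {}
    if config.encrypt:
        try:
            stage("keygen")
            key, bt_ms = crypto.generate_keys(
                config.scheme, config.key_bits, seeds["keys"]
            )
            crypto.save_keypair(key, art.key_json)
            timings["key_generation_BT"] = bt_ms
        except Exception as exc:
            raise PipelineError(f"stage 'keygen' failed: {exc}") from exc
        try:
            stage("encrypt")
            store, at_ms = crypto.encrypt_cohort(
                records, key, config.precision, seed=seeds["encrypt"]
            )
            with open(art.store_json, "w") as fh:
                json.dump({**stamp, **store}, fh)
            timings["encryption_AT"] = at_ms
        except Exception as exc:
            raise PipelineError(f"stage 'encrypt' failed: {exc}") from exc
        try:
            stage("decrypt")
            decrypted, ct_ms = crypto.decrypt_cohort(store, key)
            timings["decryption_CT"] = ct_ms
            orig = np.stack([r.features for r in records])
            back = np.stack([r.features for r in decrypted])
            err = float(np.max(np.abs(orig - back))) if len(records) else 0.0
            if err > 10.0 ** (-config.precision):
                raise PipelineError(
                    f"decrypted features deviate by {err} "
                    f"(> 1e-{config.precision})"
                )
            working = decrypted
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'decrypt' failed: {exc}") from exc
    else:
        key = None
        working = records
        store = crypto.plaintext_store(records, config.precision)
        with open(art.store_json, "w") as fh:
            json.dump({**stamp, **store}, fh)
        timings["key_generation_BT"] = 0.0
        timings["encryption_AT"] = 0.0
        timings["decryption_CT"] = 0.0

    try:
        stage("split")
        train, test = split_cohort(working, config.train_fraction, seeds["split"])
    except Exception as exc:
        raise PipelineError(f"stage 'split' failed: {exc}") from exc

    try:
        stage("train")
        model, history = run_ccrbm_wo(train, config)
        model.save(art.model_json)
        with open(art.woa_history_jsonl, "w") as fh:
            for entry in history:
                fh.write(json.dumps(entry) + "\n")
    except Exception as exc:
        raise PipelineError(f"stage 'train' failed: {exc}") from exc

    try:
        stage("evaluate")
        test_x, test_y = cohort_matrix(test)
        pred, conf = model.predict_batch(test_x)
        counts = evaluation.confusion(test_y.tolist(), pred.tolist())
        metrics = evaluation.compute_metrics(counts)
        dictionary = [
            r.features
            for r in records[: min(config.adversary_dictionary_size, len(records))]
        ]
        # the adversary draws its own randomness; it never sees the
        # encryptor's seed
        security = evaluation.security_analysis(
            store, dictionary, key=key, seed=seeds["adversary"]
        )
        report = evaluation.EvaluationReport(
            counts=counts, metrics=metrics, security=security
        )
        doc = {
            **stamp,
            **report.as_dict(),
            "predictions": [
                {"patient_id": t.patient_id, "label": int(yt), "predicted": int(yp),
                 "confidence": float(c)}
                for t, yt, yp, c in zip(test, test_y, pred, conf)
            ],
        }
        doc.pop("timings_ms", None)  # timings live in their own artifact
        with open(art.report_json, "w") as fh:
            json.dump(doc, fh, indent=1)
        with open(art.timings_json, "w") as fh:
            json.dump({**stamp, "timings_ms": timings}, fh, indent=1)
    except Exception as exc:
        raise PipelineError(f"stage 'evaluate' failed: {exc}") from exc

    stage("done")
    return art
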