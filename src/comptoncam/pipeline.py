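"""End-to-end demo pipeline: phantoms → events → pairs → training → metrics.

Configuration is a nested dict (usually loaded from one YAML file with
per-stage sections); every artifact lands under a single output
directory together with the config echo, the dataset manifest and a
JSON provenance record, so a run can be reproduced from its own output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from .dataset import NoiseSpec, SupervisedDataset, build_manifest, make_pair
from .detector import standard_geometry
from .grids import GridSpec
from .networks import NetworkSpec, build_network
from .phantoms import (
    default_rototranslations,
    enumerate_catalog,
    make_body_cylinder,
    make_source_distribution,
)
from .simulate import energy_window_filter, simulate_events
from .train_eval import TrainConfig, evaluate, train

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 7,
    "grid": {"shape": [16, 16, 32], "region_mm": [80.0, 80.0, 160.0]},
    "catalog": {"n_full": 2, "ratios": [4.0, "inf"], "n_inf_only": 1,
                "rototranslations": 1},
    "simulate": {"n_gammas": 300000, "detector": "four_module"},
    "mlem": {"input_iter": 10, "label_iter": 60},
    "noise": {"n_noisy_per_sample": 5},
    "split_fractions": [0.6, 0.2, 0.2],
    "network": {"variant": "tight_frame", "levels": 2, "base_channels": 4,
                "n_convs": 1},
    "train": {"max_epochs": 3, "learning_rate": 0.001},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        cfg = _merge(cfg, yaml.safe_load(Path(path).read_text()) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _sample_splits(n: int, fractions, rng) -> list[str]:
    counts = [int(round(f * n)) for f in fractions]
    counts[0] = n - sum(counts[1:])
    names = []
    for name, c in zip(("train", "val", "test"), counts):
        names += [name] * c
    order = rng.permutation(n)
    out = [""] * n
    for slot, idx in zip(names, order):
        out[idx] = slot
    return out


def run_pipeline(cfg: dict, out_dir: str | Path, dry_run: bool = False) -> Path:
    """Execute every stage; returns the artifact directory.

    ``dry_run`` validates the configuration (grid divisibility, catalog
    counts, split feasibility) without computing anything.
    """
    out = Path(out_dir) / time.strftime("run-%Y%m%d-%H%M%S")
    seed = int(cfg["seed"])
    master = np.random.default_rng(seed)

    grid = GridSpec.default(
        shape=tuple(cfg["grid"]["shape"]), region_mm=tuple(cfg["grid"]["region_mm"])
    )
    net_cfg = cfg["network"]
    div = 2 ** int(net_cfg.get("levels", 2))
    if any(s % div for s in grid.shape):
        raise ValueError(f"grid shape {grid.shape} not divisible by {div}")
    ratios = [float("inf") if r == "inf" else float(r) for r in cfg["catalog"]["ratios"]]
    n_roto = int(cfg["catalog"]["rototranslations"])
    specs = enumerate_catalog(
        int(cfg["catalog"]["n_full"]),
        ratios,
        int(cfg["catalog"]["n_inf_only"]),
        rototranslations=default_rototranslations()[:n_roto],
    )
    if len(specs) < 5:
        raise ValueError("catalog too small: need at least 5 samples for splits")
    if dry_run:
        log.info("dry run OK: %d samples on grid %s", len(specs), grid.shape)
        return out

    out.mkdir(parents=True)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg))
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]

    body = make_body_cylinder(grid)
    det = standard_geometry(cfg["simulate"]["detector"])
    n_gammas = int(cfg["simulate"]["n_gammas"])
    pairs = {}
    for sid, spec in enumerate(specs):
        src = make_source_distribution(body, spec.geometry, spec.ratio)
        ev = energy_window_filter(
            simulate_events(src, det, n_gammas, rng=master.integers(2**31))
        )
        log.info("stage=simulate sample=%s events=%d", spec.label, len(ev))
        pairs[sid] = make_pair(
            ev,
            grid,
            n_input_iter=int(cfg["mlem"]["input_iter"]),
            n_label_iter=int(cfg["mlem"]["label_iter"]),
        )

    noise = NoiseSpec(n_noisy_per_sample=int(cfg["noise"]["n_noisy_per_sample"]))
    n_samples = len(specs)
    fr = cfg["split_fractions"]
    n_val = max(1, int(round(fr[1] * n_samples)))
    n_test = max(1, int(round(fr[2] * n_samples)))
    n_train = n_samples - n_val - n_test
    manifest = build_manifest(
        n_base=n_samples // (1 + n_roto),
        n_rototrans=n_roto,
        noise=noise,
        split_counts=(n_train, n_val, n_test),
        seed=seed,
    )
    manifest.to_csv(out / "manifest.csv")
    dataset = SupervisedDataset.from_pairs(pairs, manifest, rng=master.integers(2**31))

    net = build_network(
        NetworkSpec(
            variant=net_cfg["variant"],
            levels=int(net_cfg.get("levels", 2)),
            base_channels=int(net_cfg.get("base_channels", 8)),
            n_convs=int(net_cfg.get("n_convs", 2)),
        ),
        rng=int(master.integers(2**31)),
    )
    tcfg = TrainConfig(
        learning_rate=float(cfg["train"]["learning_rate"]),
        max_epochs=int(cfg["train"]["max_epochs"]),
        seed=int(master.integers(2**31)),
    )
    result = train(net, dataset, tcfg)
    result.history.to_csv(out / "history.csv", index=False)
    net.save(out / "best.npz")
    metrics = evaluate(net, dataset, "test")
    metrics.to_csv(out / "test_metrics.csv", index=False)

    provenance = {
        "seed": seed,
        "config_hash": cfg_hash,
        "n_samples": n_samples,
        "images_per_split": {s: dataset.n_images(s) for s in ("train", "val", "test")},
        "best_epoch": result.best_epoch,
        "best_val_nmse": result.best_val_nmse,
        "untrained_val_nmse": result.baseline_val_nmse,
        "test_mean_nmse": float(metrics.iloc[-1]["nmse"]),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    log.info("pipeline complete: %s", out)
    return out
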