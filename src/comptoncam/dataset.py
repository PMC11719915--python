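"""Supervised dataset assembly for the denoising networks.

A *sample* is one reconstructed source distribution: the pair formed by
the 10th list-mode MLEM iterate (network input) and the 60th iterate
(label), each normalized to [0, 1].  Each sample spawns 41 additional
noisy inputs — Gaussian white noise at one of four levels whose
standard deviations are the input's dynamic range divided by 16, 20, 30
and 40 — while the label is shared untouched, so 42 images per sample.
With the full-scale catalog (71 base distributions x 5 rototranslation
variants = 355 samples) this yields 14,910 images, split 11,130 / 1,260
/ 2,520 by assigning whole samples (265 / 30 / 60) to train /
validation / test.  Noise-level assignment cycles deterministically
through the four levels (11, 10, 10, 10 variants per sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridSpec, ImageVolume
from .mlem import ConeModel, ListModeMLEM
from .simulate import EventList

__all__ = [
    "NoiseSpec",
    "DatasetManifest",
    "SupervisedDataset",
    "make_pair",
    "add_noise",
    "build_manifest",
]

SPLITS = ("train", "val", "test")


@dataclass(frozen=True)
class NoiseSpec:
    """Four-level Gaussian white-noise augmentation.

    ``divisors`` set each level's standard deviation as
    ``(max - min of the input) / divisor``; ``n_noisy_per_sample`` noisy
    copies are generated per clean sample (levels cycle 0,1,2,3,...).
    """

    divisors: tuple[float, float, float, float] = (16.0, 20.0, 30.0, 40.0)
    n_noisy_per_sample: int = 41

    def __post_init__(self) -> None:
        if len(set(self.divisors)) != 4 or any(d <= 0 for d in self.divisors):
            raise ValueError("divisors must be four distinct positive reals")
        if self.n_noisy_per_sample < 0:
            raise ValueError("n_noisy_per_sample must be >= 0")

    def level_for_variant(self, variant_id: int) -> int:
        """Noise level of noisy variant 1..n (variant 0 is the clean copy)."""
        if variant_id < 1:
            raise ValueError("variant 0 is the clean image")
        return (variant_id - 1) % 4

    def sigma(self, x: np.ndarray, level: int) -> float:
        if level not in (0, 1, 2, 3):
            raise ValueError("level must be in 0..3")
        return float((x.max() - x.min()) / self.divisors[level])


def make_pair(
    events: EventList,
    grid: GridSpec,
    n_input_iter: int = 10,
    n_label_iter: int = 60,
    cone_model: ConeModel | None = None,
    mask: np.ndarray | None = None,
) -> tuple[ImageVolume, ImageVolume]:
    """(input, label) = MLEM iterates ``n_input_iter`` and ``n_label_iter``.

    Both volumes are independently normalized to [0, 1]; a degenerate
    (constant) iterate raises.
    """
    model = ListModeMLEM(events, grid, cone_model, mask=mask)
    res = model.fit(
        n_iter=max(n_input_iter, n_label_iter),
        snapshots=(n_input_iter, n_label_iter),
    )
    return (
        res.snapshots[n_input_iter].normalized(),
        res.snapshots[n_label_iter].normalized(),
    )


def add_noise(
    x: ImageVolume | np.ndarray,
    level: int,
    rng: np.random.Generator,
    noise: NoiseSpec = NoiseSpec(),
    clamp: bool = True,
) -> ImageVolume | np.ndarray:
    """Add level-``level`` Gaussian white noise to an input image.

    The corresponding label is never touched by this function.  With
    ``clamp`` (default) the result is floored at zero, since intensities
    represent activities; disable for literal unclamped replication.
    """
    arr = x.values if isinstance(x, ImageVolume) else np.asarray(x, float)
    out = arr + rng.normal(0.0, noise.sigma(arr, level), arr.shape)
    if clamp:
        out = np.maximum(out, 0.0)
    if isinstance(x, ImageVolume):
        return ImageVolume(x.grid, np.maximum(out, 0.0) if not clamp else out)
    return out


@dataclass
class DatasetManifest:
    """Bookkeeping of every image: sample ids, noise variants, splits.

    ``entries`` has one row per image with columns ``sample_id``,
    ``base_id``, ``rototrans_id``, ``variant_id`` (0 = clean),
    ``noise_level`` (-1 for clean) and ``split``.  All variants of a
    sample share one split; rototranslations of the same base may land
    in different splits, so each split sees mostly new distributions.
    """

    entries: pd.DataFrame
    seed: int
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def split_counts(self) -> dict[str, int]:
        c = self.entries["split"].value_counts()
        return {s: int(c.get(s, 0)) for s in SPLITS}

    def sample_ids(self, split: str) -> list[int]:
        e = self.entries
        return sorted(e.loc[e["split"] == split, "sample_id"].unique().tolist())

    def __len__(self) -> int:
        return len(self.entries)

    def to_csv(self, path) -> None:
        """Write entries as CSV plus a JSON sidecar with seed/noise plan."""
        import json
        from pathlib import Path

        path = Path(path)
        self.entries.to_csv(path, index=False)
        sidecar = {
            "seed": self.seed,
            "noise_divisors": list(self.noise.divisors),
            "n_noisy_per_sample": self.noise.n_noisy_per_sample,
            "split_counts": self.split_counts(),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def build_manifest(
    n_base: int = 71,
    n_rototrans: int = 4,
    noise: NoiseSpec = NoiseSpec(),
    split_counts: tuple[int, int, int] = (265, 30, 60),
    seed: int = 0,
    base_kinds: list[str] | None = None,
) -> DatasetManifest:
    """Assign samples to splits and enumerate all image variants.

    ``split_counts`` are whole *samples* per split and must sum to
    ``n_base * (1 + n_rototrans)``.  With the full-scale defaults
    (71 base, 4 rototranslations, 41 noisy variants, 265/30/60) the
    image totals are 11,130 / 1,260 / 2,520 = 14,910.  If ``base_kinds``
    gives a class label per base distribution, the split assignment is
    stratified on it.
    """
    n_samples = n_base * (1 + n_rototrans)
    if sum(split_counts) != n_samples:
        raise ValueError(
            f"split_counts {split_counts} sum to {sum(split_counts)}, "
            f"but n_base*(1+n_rototrans) = {n_base}*{1 + n_rototrans} = {n_samples}"
        )
    if base_kinds is not None and len(base_kinds) != n_base:
        raise ValueError("base_kinds must have one label per base distribution")

    rng = np.random.default_rng(seed)
    samples = [(b, t) for t in range(1 + n_rototrans) for b in range(n_base)]
    if base_kinds is None:
        order = rng.permutation(n_samples)
        ordered = [samples[i] for i in order]
    else:
        # systematic stratification: shuffle within each class, then order
        # all samples by within-class rank fraction so any contiguous slice
        # has near-proportional class composition
        groups: dict[str, list[tuple[int, int]]] = {}
        for s in samples:
            groups.setdefault(base_kinds[s[0]], []).append(s)
        keyed = []
        for k in sorted(groups):
            g = groups[k]
            rng.shuffle(g)
            for i, s in enumerate(g):
                keyed.append(((i + 0.5) / len(g), k, s))
        keyed.sort(key=lambda t: (t[0], t[1]))
        ordered = [s for _, _, s in keyed]

    split_of: dict[tuple[int, int], str] = {}
    pos = 0
    for name, count in zip(SPLITS, split_counts):
        for s in ordered[pos : pos + count]:
            split_of[s] = name
        pos += count

    rows = []
    for sid, (b, t) in enumerate(samples):
        split = split_of[(b, t)]
        rows.append((sid, b, t, 0, -1, split))
        for v in range(1, noise.n_noisy_per_sample + 1):
            rows.append((sid, b, t, v, noise.level_for_variant(v), split))
    entries = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "base_id",
            "rototrans_id",
            "variant_id",
            "noise_level",
            "split",
        ],
    )
    return DatasetManifest(entries=entries, seed=seed, noise=noise)


@dataclass
class SupervisedDataset:
    """In-memory (input, label) images grouped by split.

    ``items`` maps each split name to a list of ``(input, label)`` array
    pairs.  Built from clean per-sample pairs plus the manifest's noise
    plan; labels of noisy variants are the clean sample's label array
    (shared, never perturbed).
    """

    items: dict[str, list[tuple[np.ndarray, np.ndarray]]]
    grid: GridSpec

    @classmethod
    def from_pairs(
        cls,
        pairs: dict[int, tuple[ImageVolume, ImageVolume]],
        manifest: DatasetManifest,
        rng: np.random.Generator | int = 0,
        clamp: bool = True,
    ) -> "SupervisedDataset":
        """Materialize every manifest row whose sample id is in ``pairs``."""
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(int(rng))
        items: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {
            s: [] for s in SPLITS
        }
        grid = next(iter(pairs.values()))[0].grid
        for row in manifest.entries.itertuples(index=False):
            if row.sample_id not in pairs:
                continue
            inp, lab = pairs[row.sample_id]
            if row.variant_id == 0:
                x = inp.values
            else:
                x = add_noise(
                    inp.values, row.noise_level, rng, manifest.noise, clamp=clamp
                )
            items[row.split].append((x, lab.values))
        return cls(items=items, grid=grid)

    def n_images(self, split: str) -> int:
        return len(self.items[split])
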