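"""Dataset bookkeeping and file formats.

Manifests are TSV tables pairing images with masks by filename stem
(``<variety>_<surface>_<replicate>[_aug<k>]``). Masks are single-channel
8-bit indexed PNGs with labels {0, 1, 2}. Dataset splitting follows the
7:2:1 train/test/validation convention with largest-remainder
apportionment for counts that do not divide exactly; by default all
augmented variants of one source image are kept in the same partition
(grouped splitting) to prevent leakage, with an ungrouped mode that
splits the expanded pool directly.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .traits import ImageTraits

__all__ = ["SplitAssignment", "apportion", "split_dataset",
           "read_mask", "write_mask", "read_image", "write_image",
           "read_manifest", "write_manifest",
           "write_traits_csv", "read_traits_csv", "write_sample"]

MANIFEST_COLUMNS = ["sample_id", "image_path", "mask_path", "variety",
                    "surface", "replicate", "split"]
PARTITIONS = ("train", "test", "val")

_PALETTE = [0, 0, 0, 230, 60, 60, 60, 120, 230] + [0] * (256 * 3 - 9)

_AUG_RE = re.compile(r"^(?P<stem>.+?)(?:_aug\d+)?$")


def source_stem(sample_id: str) -> str:
    """Strip an ``_aug<k>`` suffix: augmented variants share their source."""
    return _AUG_RE.match(sample_id)["stem"]


@dataclass
class SplitAssignment:
    assignment: dict[str, str]       # sample_id -> partition
    sizes: dict[str, int]
    ratios: tuple[float, float, float]
    seed: int

    def ids(self, partition: str) -> list[str]:
        return [k for k, v in self.assignment.items() if v == partition]


def apportion(n: int, ratios) -> tuple[int, ...]:
    """Largest-remainder apportionment of ``n`` items by ``ratios``."""
    ratios = np.asarray(ratios, dtype=float)
    if (ratios <= 0).any():
        raise ValueError("ratios must be positive")
    if n < len(ratios):
        raise ValueError(f"cannot split {n} items into {len(ratios)} partitions")
    quotas = n * ratios / ratios.sum()
    base = np.floor(quotas).astype(int)
    rem = quotas - base
    short = n - base.sum()
    # ties broken toward the earlier partition (stable argsort on -remainder)
    for i in np.argsort(-rem, kind="stable")[:short]:
        base[i] += 1
    return tuple(int(b) for b in base)


def split_dataset(ids_or_n, ratios=(7, 2, 1), seed: int = 0,
                  grouped: bool = True) -> SplitAssignment:
    """Assign samples to train/test/val partitions.

    ``ids_or_n`` is either a total count (an integer: ids become
    ``s0000..``) or a sequence of sample ids. With ``grouped=True``
    (default) splitting operates on source stems so augmented siblings
    never straddle partitions; ``grouped=False`` reproduces splitting of
    the already-expanded pool.
    """
    if isinstance(ids_or_n, (int, np.integer)):
        ids = [f"s{i:05d}" for i in range(int(ids_or_n))]
    else:
        ids = [str(i) for i in ids_or_n]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
    units: list[str] | dict[str, list[str]]
    if grouped:
        groups: dict[str, list[str]] = {}
        for i in ids:
            groups.setdefault(source_stem(i), []).append(i)
        unit_keys = sorted(groups)
    else:
        groups = {i: [i] for i in ids}
        unit_keys = sorted(groups)
    sizes = apportion(len(unit_keys), ratios)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(unit_keys))
    assignment: dict[str, str] = {}
    bounds = np.cumsum((0,) + sizes)
    for part, lo, hi in zip(PARTITIONS, bounds[:-1], bounds[1:]):
        for j in perm[lo:hi]:
            for sid in groups[unit_keys[j]]:
                assignment[sid] = part
    part_sizes = {p: sum(1 for v in assignment.values() if v == p) for p in PARTITIONS}
    r = np.asarray(ratios, dtype=float)
    return SplitAssignment(assignment=assignment, sizes=part_sizes,
                           ratios=tuple(r / r.sum()), seed=seed)


# ---------------------------------------------------------------------------
# masks and images
# ---------------------------------------------------------------------------

def write_mask(mask: np.ndarray, path) -> None:
    """Write a {0,1,2} label mask as indexed 8-bit PNG."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1, 2)).all():
        raise ValueError("mask labels outside {0, 1, 2}")
    im = Image.fromarray(mask.astype(np.uint8), mode="P")
    im.putpalette(_PALETTE)
    im.save(path, format="PNG")


def read_mask(path) -> np.ndarray:
    im = Image.open(path)
    if im.mode not in ("P", "L"):
        raise ValueError(f"{path}: expected single-channel indexed mask, got mode {im.mode}")
    arr = np.asarray(im, dtype=np.uint8)
    if not np.isin(arr, (0, 1, 2)).all():
        raise ValueError(f"{path}: mask labels outside {{0, 1, 2}}")
    return arr


def write_image(image: np.ndarray, path) -> None:
    path = Path(path)
    im = Image.fromarray(np.asarray(image, dtype=np.uint8))
    if path.suffix.lower() in (".jpg", ".jpeg"):
        im.save(path, quality=95)
    else:
        im.save(path)


def read_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"), dtype=np.uint8)


def write_sample(sample, out_dir, sample_id: str) -> tuple[Path, Path]:
    """Write image + mask + JSON object sidecar; returns the two paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img_path = out_dir / f"{sample_id}.png"
    mask_path = out_dir / f"{sample_id}_mask.png"
    write_image(sample.image, img_path)
    write_mask(sample.mask, mask_path)
    (out_dir / f"{sample_id}.json").write_text(json.dumps(
        {"objects": [list(map(float, o)) for o in sample.objects]}, indent=1))
    return img_path, mask_path


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def write_manifest(df: pd.DataFrame, path) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    df[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)


def read_manifest(path, check_paths: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in manifest")
    if check_paths:
        root = Path(path).parent
        for col in ("image_path", "mask_path"):
            for p in df[col]:
                full = Path(p) if Path(p).is_absolute() else root / p
                if not full.exists():
                    raise FileNotFoundError(f"manifest references missing file {p}")
        for img, msk in zip(df["image_path"], df["mask_path"]):
            if Path(img).stem != Path(msk).stem.removesuffix("_mask"):
                raise ValueError(f"image/mask stem mismatch: {img} vs {msk}")
    return df


# ---------------------------------------------------------------------------
# traits tables
# ---------------------------------------------------------------------------

DETAIL_COLUMNS = ["sample_id", "surface", "object_id", "length_px",
                  "width_px", "area_px2", "border_flag"]
SUMMARY_COLUMNS = ["sample_id", "surface", "stoma_count", "mean_length",
                   "mean_width", "mean_area"]


def write_traits_csv(traits: list[ImageTraits], path,
                     summary_path=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One detail row per detected object plus a per-image summary table."""
    rows, summaries = [], []
    for t in traits:
        for j, r in enumerate(t.records):
            rows.append({"sample_id": t.sample_id, "surface": t.surface,
                         "object_id": j, "length_px": r.length,
                         "width_px": r.width, "area_px2": r.area,
                         "border_flag": r.border_flag})
        summaries.append({"sample_id": t.sample_id, "surface": t.surface,
                          **{k: v for k, v in t.summary().items()}})
    detail = pd.DataFrame(rows, columns=DETAIL_COLUMNS)
    summary = pd.DataFrame(summaries, columns=SUMMARY_COLUMNS)
    detail.to_csv(path, index=False)
    if summary_path is not None:
        summary.to_csv(summary_path, index=False)
    return detail, summary


def read_traits_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
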