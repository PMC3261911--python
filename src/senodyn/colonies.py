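"""Colony-formation image analysis.

Quantifies crystal-violet plate images in three steps: threshold to a
binary grid, label connected foreground clusters with the Hoshen-Kopelman
algorithm (single raster pass with union-find label equivalence), and
summarize colony count, covered area fraction and the colony size
distribution.  Input is a single-well grayscale image; colony polarity
(bright- or dark-staining) is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BinaryGrid",
    "ColonyStats",
    "to_grayscale",
    "load_image",
    "otsu_threshold",
    "binarize",
    "hoshen_kopelman_label",
    "colony_statistics",
    "analyze_plate",
]


@dataclass(frozen=True)
class BinaryGrid:
    """Thresholded image: strictly binary pixels plus provenance."""

    pixels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.isin(px, (0, 1)).all():
            raise ValueError("pixels must be strictly binary")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ColonyStats:
    """Colony summary after speck filtering."""

    n_colonies: int
    area_fraction: float
    sizes: np.ndarray  # pixel count per kept colony, descending
    size_histogram: tuple[np.ndarray, np.ndarray]  # (counts, bin_edges)
    min_size: int

    def to_dict(self) -> dict:
        counts, edges = self.size_histogram
        return {
            "n_colonies": int(self.n_colonies),
            "area_fraction": float(self.area_fraction),
            "sizes": [int(s) for s in self.sizes],
            "size_histogram": {
                "counts": [int(c) for c in counts],
                "bin_edges": [float(e) for e in edges],
            },
            "min_size": int(self.min_size),
        }


def to_grayscale(image: np.ndarray, channel: int | str = "luminance") -> np.ndarray:
    """Collapse an (H, W, 3/4) color image to one channel.

    ``channel`` is an RGB index or 'luminance' (Rec. 601 weights); plates
    are often photographed in color, and the choice is recorded upstream
    in the binarization provenance.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        return arr
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise ValueError(f"cannot interpret image of shape {arr.shape}")
    rgb = arr[..., :3]
    if channel == "luminance":
        return rgb @ np.array([0.299, 0.587, 0.114])
    return rgb[..., int(channel)]


def load_image(path, channel: int | str = "luminance") -> np.ndarray:
    """Read a PNG/TIFF image into a grayscale float array."""
    from PIL import Image

    with Image.open(path) as img:
        arr = np.asarray(img, dtype=float)
    return to_grayscale(arr, channel)


def otsu_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Histogram threshold maximizing the between-class variance."""
    img = np.asarray(image, dtype=float).ravel()
    lo, hi = img.min(), img.max()
    if hi <= lo:
        return lo
    counts, edges = np.histogram(img, bins=n_bins, range=(lo, hi))
    mids = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    csum = np.cumsum(counts * mids)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = csum / w0
        mu1 = (csum[-1] - csum) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between = np.where((w0 > 0) & (w1 > 0), between, -np.inf)
    return float(mids[int(np.argmax(between))])


def binarize(
    image: np.ndarray,
    threshold: float | str = "otsu",
    polarity: str = "bright",
    source: str | None = None,
) -> BinaryGrid:
    """Threshold a single-channel image into a :class:`BinaryGrid`.

    ``polarity='bright'`` marks pixels at or above the threshold as
    foreground (colonies stain bright in the synthetic plates);
    'dark' inverts the rule for dark-on-light staining.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ValueError(
            "binarize expects a single-channel image; use to_grayscale() "
            "with an explicit channel choice for color input"
        )
    if polarity not in ("bright", "dark"):
        raise ValueError("polarity must be 'bright' or 'dark'")
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold keyword {threshold!r}")
        thr = otsu_threshold(arr)
    else:
        thr = float(threshold)
        if not (arr.min() <= thr <= arr.max()) and arr.min() != arr.max():
            raise ValueError(
                f"threshold {thr} outside intensity range [{arr.min()}, {arr.max()}]"
            )
    mask = arr >= thr if polarity == "bright" else arr < thr
    return BinaryGrid(
        pixels=mask.astype(np.uint8),
        provenance={"source": source, "threshold": thr, "polarity": polarity},
    )


def hoshen_kopelman_label(
    grid: BinaryGrid | np.ndarray, connectivity: int = 8
) -> np.ndarray:
    """Hoshen-Kopelman connected-component labeling.

    Single raster pass assigning provisional labels and recording label
    equivalences in a union-find forest (path halving), followed by a
    dense renumbering to labels 1..n; 0 is background.  The resulting
    partition is identical to a flood fill for the same connectivity.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    px = grid.pixels if isinstance(grid, BinaryGrid) else np.asarray(grid)
    if not np.isin(px, (0, 1)).all():
        raise ValueError("grid must be binary")
    h, w = px.shape
    labels = np.zeros((h, w), dtype=np.int64)
    parent = [0]  # parent[i] == i marks a root

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]  # path halving
            x = parent[x]
        return x

    def union(a: int, b: int) -> int:
        ra, rb = find(a), find(b)
        if ra != rb:
            if ra > rb:
                ra, rb = rb, ra
            parent[rb] = ra
        return ra

    next_label = 1
    for i in range(h):
        row = px[i]
        for j in range(w):
            if not row[j]:
                continue
            neigh = []
            if j > 0 and labels[i, j - 1]:
                neigh.append(labels[i, j - 1])
            if i > 0:
                if labels[i - 1, j]:
                    neigh.append(labels[i - 1, j])
                if connectivity == 8:
                    if j > 0 and labels[i - 1, j - 1]:
                        neigh.append(labels[i - 1, j - 1])
                    if j + 1 < w and labels[i - 1, j + 1]:
                        neigh.append(labels[i - 1, j + 1])
            if not neigh:
                parent.append(next_label)
                labels[i, j] = next_label
                next_label += 1
            else:
                root = find(int(neigh[0]))
                for other in neigh[1:]:
                    root = union(root, int(other))
                labels[i, j] = root

    # resolve equivalences and renumber densely in raster order
    remap: dict[int, int] = {}
    out = np.zeros_like(labels)
    nxt = 1
    flat_in, flat_out = labels.ravel(), out.ravel()
    for idx in range(flat_in.size):
        lab = flat_in[idx]
        if lab:
            root = find(int(lab))
            if root not in remap:
                remap[root] = nxt
                nxt += 1
            flat_out[idx] = remap[root]
    return out


def colony_statistics(labels: np.ndarray, min_size: int = 5) -> ColonyStats:
    """Count, area fraction and size distribution of labeled colonies.

    Clusters smaller than ``min_size`` pixels are discarded as staining
    specks before any statistic is computed.
    """
    if min_size < 1:
        raise ValueError("min_size must be at least 1")
    labels = np.asarray(labels)
    sizes = np.bincount(labels.ravel())[1:]
    kept = np.sort(sizes[sizes >= min_size])[::-1].astype(int)
    area_fraction = float(kept.sum() / labels.size)
    if kept.size:
        counts, edges = np.histogram(kept, bins="auto")
    else:
        counts, edges = np.zeros(1, dtype=int), np.array([0.0, 1.0])
    return ColonyStats(
        n_colonies=int(kept.size),
        area_fraction=area_fraction,
        sizes=kept,
        size_histogram=(counts, edges),
        min_size=min_size,
    )


def analyze_plate(
    image: np.ndarray,
    threshold: float | str = "otsu",
    polarity: str = "bright",
    connectivity: int = 8,
    min_size: int = 5,
) -> ColonyStats:
    """Full pipeline: threshold, Hoshen-Kopelman labeling, statistics."""
    grid = binarize(image, threshold=threshold, polarity=polarity)
    return colony_statistics(hoshen_kopelman_label(grid, connectivity), min_size)
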