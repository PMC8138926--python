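"""Seeded simulators for the pipeline's raw inputs.

Brightfield DAB/hematoxylin appearance is emulated on a single 8-bit gray
channel: stained nuclei are dark discs, unstained nuclei are paler discs,
the background is near-white, and every pixel carries Gaussian sensor noise.
Dot-like nuclei (a single punctate focus of stain inside an otherwise
unstained nucleus, the pattern counted as loss) are rendered as an unstained
disc with one small interior stained disc. Internal-control cells
(endothelium/lymphocytes, which always retain the stain) are rendered stained
regardless of the tumor's status. FISH input is simulated as per-nucleus
red/green signal-count tables with an exact number of deleted-pattern nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import disk

TRUTH_CLASSES = ("TUMOR_STAINED", "TUMOR_DOTLIKE", "TUMOR_NEGATIVE", "CONTROL_POSITIVE")
GROUND_TRUTH_COLUMNS = ["nucleus_id", "row", "col", "radius", "truth_class"]
FISH_COLUMNS = ["nucleus_id", "probe_set", "n_red", "n_green"]

#: proportion of a dot-like nucleus' area covered by its stained dot (< 0.10)
DOT_AREA_FRACTION = 0.05


@dataclass(frozen=True)
class SimImageParams:
    """Parameters of one simulated stained-tissue field.

    Gray levels follow the brightfield convention: stain is dark
    (``mean_stained_gray < mean_unstained_gray < background_gray``).
    """

    image_size: int = 256
    n_tumor_nuclei: int = 40
    n_control_cells: int = 4
    stained_fraction: float = 0.5
    dotlike_fraction: float = 0.0
    mean_stained_gray: float = 90.0
    mean_unstained_gray: float = 180.0
    background_gray: float = 235.0
    noise_sd: float = 4.0
    nucleus_radius_range: tuple[int, int] = (6, 9)
    seed: int = 0

    def validate(self) -> None:
        if not (self.mean_stained_gray < self.mean_unstained_gray < self.background_gray):
            raise ValueError(
                "brightfield convention violated: need "
                "mean_stained_gray < mean_unstained_gray < background_gray"
            )
        if self.n_tumor_nuclei < 1:
            raise ValueError("n_tumor_nuclei must be >= 1")
        if self.n_control_cells < 0:
            raise ValueError("n_control_cells must be >= 0")
        if not (0.0 <= self.stained_fraction <= 1.0):
            raise ValueError("stained_fraction must lie in [0, 1]")
        if not (0.0 <= self.dotlike_fraction <= 1.0):
            raise ValueError("dotlike_fraction must lie in [0, 1]")
        lo, hi = self.nucleus_radius_range
        if not (0 < lo <= hi):
            raise ValueError("nucleus_radius_range must satisfy 0 < lo <= hi")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class CellGroundTruth:
    """Per-nucleus truth behind a simulated field (0-based row/col centers)."""

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=GROUND_TRUTH_COLUMNS))

    def nucleus_mask(self, image_shape: tuple[int, int], nucleus_id: int) -> np.ndarray:
        row = self.table.loc[self.table["nucleus_id"] == nucleus_id].iloc[0]
        mask = np.zeros(image_shape, dtype=bool)
        rr, cc = disk((row["row"], row["col"]), row["radius"], shape=image_shape)
        mask[rr, cc] = True
        return mask

    def tumor_mask(self, image_shape: tuple[int, int]) -> np.ndarray:
        mask = np.zeros(image_shape, dtype=bool)
        for _, row in self.table.iterrows():
            if row["truth_class"] != "CONTROL_POSITIVE":
                rr, cc = disk((row["row"], row["col"]), row["radius"], shape=image_shape)
                mask[rr, cc] = True
        return mask


def _place_nuclei(rng: np.random.Generator, params: SimImageParams, n: int,
                  max_attempts: int = 20000) -> list[tuple[int, int, int]]:
    """Rejection-sample non-overlapping disc placements away from the border."""
    lo, hi = params.nucleus_radius_range
    placed: list[tuple[int, int, int]] = []
    attempts = 0
    while len(placed) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} non-overlapping nuclei of radius {lo}-{hi} "
                f"in a {params.image_size}px field within {max_attempts} attempts"
            )
        attempts += 1
        r = int(rng.integers(lo, hi + 1))
        margin = r + 1  # nuclei must not overlap the image border
        row = int(rng.integers(margin, params.image_size - margin))
        col = int(rng.integers(margin, params.image_size - margin))
        if all(
            (row - row0) ** 2 + (col - col0) ** 2 > (r + rad0 + 1) ** 2
            for row0, col0, rad0 in placed
        ):
            placed.append((row, col, r))
    return placed


def simulate_field(params: SimImageParams) -> tuple[np.ndarray, CellGroundTruth]:
    """Render one 8-bit field and its ground truth.

    Exactly ``round(stained_fraction * n_tumor_nuclei)`` tumor nuclei are
    stained; of the remaining unstained tumor nuclei,
    ``round(dotlike_fraction * n_unstained)`` carry a single interior stained
    dot. Control cells are always stained. Deterministic for a given params
    (including seed).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_total = params.n_tumor_nuclei + params.n_control_cells
    placements = _place_nuclei(rng, params, n_total)

    n_stained = int(np.rint(params.stained_fraction * params.n_tumor_nuclei))
    n_unstained = params.n_tumor_nuclei - n_stained
    n_dot = int(np.rint(params.dotlike_fraction * n_unstained))
    classes = (
        ["TUMOR_STAINED"] * n_stained
        + ["TUMOR_DOTLIKE"] * n_dot
        + ["TUMOR_NEGATIVE"] * (n_unstained - n_dot)
    )
    order = rng.permutation(params.n_tumor_nuclei)
    classes = [classes[i] for i in order] + ["CONTROL_POSITIVE"] * params.n_control_cells

    shape = (params.image_size, params.image_size)
    image = np.full(shape, params.background_gray, dtype=np.float64)
    rows = []
    for nucleus_id, ((row, col, radius), cls) in enumerate(zip(placements, classes)):
        body_gray = (
            params.mean_stained_gray
            if cls in ("TUMOR_STAINED", "CONTROL_POSITIVE")
            else params.mean_unstained_gray
        )
        rr, cc = disk((row, col), radius, shape=shape)
        image[rr, cc] = body_gray
        if cls == "TUMOR_DOTLIKE":
            # shrink the rasterized dot until it covers < dot_area_fraction_max
            # of the nucleus' actual pixel count (down to a single pixel)
            dot_r = max(0.5, radius * np.sqrt(DOT_AREA_FRACTION))
            drr, dcc = disk((row, col), dot_r, shape=shape)
            while len(drr) > 0.08 * len(rr) and dot_r > 0.5:
                dot_r = max(0.5, dot_r - 0.5)
                drr, dcc = disk((row, col), dot_r, shape=shape)
            image[drr, dcc] = params.mean_stained_gray
        rows.append(
            {"nucleus_id": nucleus_id, "row": row, "col": col, "radius": radius,
             "truth_class": cls}
        )

    # truncated Gaussian sensor noise: excursions are capped at 3 sd so the
    # stained / unstained / background gray populations stay disjoint
    noise = rng.normal(0.0, params.noise_sd, size=shape)
    if params.noise_sd > 0:
        np.clip(noise, -3 * params.noise_sd, 3 * params.noise_sd, out=noise)
    image = np.clip(np.rint(image + noise), 0, 255).astype(np.uint8)
    truth = CellGroundTruth(pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS))
    return image, truth


def simulate_case_fields(
    case_label: str,
    n_fields: int = 3,
    base_params: SimImageParams | None = None,
    seed: int = 0,
    nl_stained_fraction: float = 0.05,
    nr_stained_fraction: float = 0.85,
    nl_dotlike_fraction: float = 0.2,
) -> list[tuple[np.ndarray, CellGroundTruth]]:
    """Simulate the fields of one case with a known NR/NL ground truth.

    Mirrors the acquisition protocol of scoring three randomly selected fields
    per section: NL (nuclear loss) cases are drawn with a stained fraction well
    below the positive rule's 25% region, NR (retention) cases well above it.
    Per-field seeds are derived deterministically from the case seed.
    """
    if case_label not in ("NR", "NL"):
        raise ValueError(f"case_label must be 'NR' or 'NL', got {case_label!r}")
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    base = base_params if base_params is not None else SimImageParams()
    if case_label == "NL":
        stained, dotlike = nl_stained_fraction, nl_dotlike_fraction
    else:
        stained, dotlike = nr_stained_fraction, 0.0
    field_seeds = np.random.SeedSequence(seed).generate_state(n_fields) % (2**31)
    out = []
    for s in field_seeds:
        params = replace(base, stained_fraction=stained, dotlike_fraction=dotlike,
                         seed=int(s))
        out.append(simulate_field(params))
    return out


def simulate_fish_table(
    deleted_fraction: float,
    n_nuclei: int,
    seed: int = 0,
    probe_set: str = "P1_1p36_1q25",
) -> pd.DataFrame:
    """Simulate a per-nucleus FISH signal-count table for one probe set.

    Exactly ``round(deleted_fraction * n_nuclei)`` nuclei carry the deleted
    pattern (one red target, two green control signals); the remainder are
    disomic (two red, two green). Row order is shuffled by the seed.
    """
    if not (0.0 <= deleted_fraction <= 1.0):
        raise ValueError("deleted_fraction must lie in [0, 1]")
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    n_deleted = int(np.rint(deleted_fraction * n_nuclei))
    n_red = np.array([1] * n_deleted + [2] * (n_nuclei - n_deleted))
    rng = np.random.default_rng(seed)
    n_red = n_red[rng.permutation(n_nuclei)]
    return pd.DataFrame(
        {
            "nucleus_id": np.arange(n_nuclei),
            "probe_set": probe_set,
            "n_red": n_red,
            "n_green": 2,
        },
        columns=FISH_COLUMNS,
    )
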