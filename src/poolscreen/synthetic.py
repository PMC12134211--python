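"""Synthetic mother-machine screen data with known ground truth.

Three generators cover the inputs of the analysis pipeline:

* :func:`gen_genotyping` — per-trap, per-round, per-channel genotyping
  signals for a library read out by sequential 4-colour probing, with
  configurable per-round symbol errors, no-signal traps, double-signal
  (two-clone) traps, Gaussian pixel background and bright blobs.  Two
  fidelities: a fast "table" mode (total intensity and above-threshold
  pixel count per trap/round/channel) and an "image" mode (small
  per-trap tiles with rendered Gaussian blobs).  Both feed the same
  decoder entry points.
* :func:`gen_phenotyping` — tracked single-cell observations for
  lineages whose post-chloramphenicol total fluorescence follows the
  single- or double-exponential maturation model, with growth and
  division, measurement noise and inter-trap bleed-through.
* :func:`gen_amplicon` — FASTQ reads each embedding one barcode in a
  fixed flank context, for exact-match counting.

Every generator is deterministic under its seed and returns a ground
truth object alongside the data so that recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .barcodes import BarcodeSeq
from .codebook import Codebook, CodebookSpec, build_codebook, corrupt_words

__all__ = [
    "GenotypingSimConfig",
    "PhenoSimConfig",
    "StrainKinetics",
    "GenotypingGroundTruth",
    "PhenoGroundTruth",
    "gen_genotyping",
    "render_trap_tiles",
    "gen_phenotyping",
    "gen_amplicon",
    "AMPLICON_FLANK5",
    "AMPLICON_FLANK3",
]

CATEGORY_EMPTY = "empty"
CATEGORY_NO_SIGNAL = "no_signal"
CATEGORY_DOUBLE = "double_signal"
CATEGORY_NORMAL = "normal"


@dataclass(frozen=True)
class GenotypingSimConfig:
    """Conditions of a simulated genotyping experiment.

    Defaults mirror a 4000-trap chip probed over 7 rounds in 4 colours
    with a library of 85 barcodes.  ``p_round_error`` defaults to the
    0.038 per-trap per-round rate measured in situ.  ``bg_mean``/``bg_sd``
    parameterise the Gaussian pixel background (and, in table mode, the
    per-channel background totals directly).
    """

    n_traps: int = 4000
    occupancy_prob: float = 0.80
    n_barcodes: int = 85
    barcode_freqs: tuple[float, ...] | None = None
    n_rounds: int = 7
    n_colors: int = 4
    p_round_error: float = 0.038
    p_no_signal: float = 0.15
    p_double_signal: float = 0.05
    bg_mean: float = 100.0
    bg_sd: float = 10.0
    blob_intensity_scale: float = 5000.0
    blob_sigma_px: float = 1.5
    trap_shape_px: tuple[int, int] = (40, 16)
    area_min_px: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("occupancy_prob", "p_round_error", "p_no_signal", "p_double_signal"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_no_signal + self.p_double_signal > 1.0:
            raise ValueError("p_no_signal + p_double_signal exceeds 1")
        if self.n_colors < 2 or self.n_rounds < 1:
            raise ValueError("need n_colors >= 2 and n_rounds >= 1")
        if self.n_barcodes < 1 or self.n_traps < 1:
            raise ValueError("n_barcodes and n_traps must be positive")
        if self.barcode_freqs is not None:
            f = np.asarray(self.barcode_freqs, dtype=float)
            if f.shape != (self.n_barcodes,):
                raise ValueError("barcode_freqs length must equal n_barcodes")
            if abs(f.sum() - 1.0) > 1e-9 or (f < 0).any():
                raise ValueError("barcode_freqs must be nonnegative and sum to 1")


@dataclass
class GenotypingGroundTruth:
    """Per-trap truth of a genotyping simulation.

    ``traps`` columns: trap_id, occupied, category, barcode_id,
    barcode_index, true_word, rendered_word, n_wrong_rounds,
    barcode_id2 (second clone of a double-signal trap, else "").
    Words are strings of symbol digits; "" where not applicable.
    """

    traps: pd.DataFrame
    codebook: Codebook
    config: GenotypingSimConfig

    def category_counts(self) -> pd.Series:
        occ = self.traps[self.traps.occupied]
        return occ.category.value_counts()


def _word_str(w: np.ndarray) -> str:
    return "".join(str(int(s)) for s in w)


def gen_genotyping(
    config: GenotypingSimConfig,
    codebook: Codebook | None = None,
    mode: str = "table",
) -> tuple[pd.DataFrame | np.ndarray, GenotypingGroundTruth]:
    """Simulate one genotyping experiment.

    In ``table`` mode the first return value is a DataFrame with one row
    per (occupied trap, round, channel): columns ``trap_id, round,
    channel, total_intensity, n_pixels``.  Non-signal channels carry
    Gaussian background totals and zero above-threshold pixels; signal
    channels carry a bright lognormally scattered blob total.  In
    ``image`` mode it is a float32 array of shape
    (n_occupied, n_rounds, n_colors, rows, cols) of rendered tiles, in
    the order of the occupied trap ids in the ground truth.

    For each occupied, signal-producing trap and round, the true colour
    is rendered with probability 1 - p_round_error and a uniformly
    chosen wrong colour otherwise.  Double-signal traps carry two
    distinct barcodes whose colours are both rendered each round.
    """
    if mode not in ("table", "image"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(config.seed)
    if codebook is None:
        codebook = build_codebook(
            CodebookSpec(
                n_codes=config.n_barcodes,
                n_rounds=config.n_rounds,
                n_colors=config.n_colors,
                seed=config.seed,
            )
        )
    if len(codebook) != config.n_barcodes:
        raise ValueError("codebook size does not match n_barcodes")
    n, R, C = config.n_traps, config.n_rounds, config.n_colors
    freqs = (
        np.full(config.n_barcodes, 1.0 / config.n_barcodes)
        if config.barcode_freqs is None
        else np.asarray(config.barcode_freqs, dtype=float)
    )

    occupied = rng.random(n) < config.occupancy_prob
    u = rng.random(n)
    category = np.where(
        ~occupied,
        CATEGORY_EMPTY,
        np.where(
            u < config.p_no_signal,
            CATEGORY_NO_SIGNAL,
            np.where(u < config.p_no_signal + config.p_double_signal, CATEGORY_DOUBLE, CATEGORY_NORMAL),
        ),
    )
    is_normal = category == CATEGORY_NORMAL
    is_double = category == CATEGORY_DOUBLE

    barcode_index = np.full(n, -1, dtype=np.int64)
    barcode_index[is_normal | is_double] = rng.choice(
        config.n_barcodes, size=int((is_normal | is_double).sum()), p=freqs
    )
    barcode_index2 = np.full(n, -1, dtype=np.int64)
    for i in np.flatnonzero(is_double):
        while True:
            j = int(rng.choice(config.n_barcodes, p=freqs))
            if j != barcode_index[i]:
                barcode_index2[i] = j
                break

    true_words = np.full((n, R), -1, dtype=np.int16)
    rendered = np.full((n, R), -1, dtype=np.int16)
    sel = is_normal
    true_words[sel] = codebook.codewords[barcode_index[sel]]
    rendered[sel] = corrupt_words(true_words[sel], config.p_round_error, C, rng)
    n_wrong = np.where(sel, (true_words != rendered).sum(axis=1), 0)
    # double traps render both clones' true colours, uncorrupted
    true_words[is_double] = codebook.codewords[barcode_index[is_double]]
    rendered[is_double] = true_words[is_double]
    rendered2 = np.full((n, R), -1, dtype=np.int16)
    rendered2[is_double] = codebook.codewords[barcode_index2[is_double]]

    occ_ids = np.flatnonzero(occupied)
    if mode == "table":
        signals = _render_table(config, rng, occ_ids, rendered, rendered2)
    else:
        signals = render_trap_tiles(config, rng, occ_ids, rendered, rendered2)

    ids = np.array(codebook.ids)
    traps = pd.DataFrame(
        {
            "trap_id": np.arange(n),
            "occupied": occupied,
            "category": category,
            "barcode_id": np.where(barcode_index >= 0, ids[barcode_index], ""),
            "barcode_index": barcode_index,
            "true_word": [
                _word_str(true_words[i]) if category[i] in (CATEGORY_NORMAL, CATEGORY_DOUBLE) else ""
                for i in range(n)
            ],
            "rendered_word": [
                _word_str(rendered[i]) if category[i] == CATEGORY_NORMAL else ""
                for i in range(n)
            ],
            "n_wrong_rounds": n_wrong,
            "barcode_id2": np.where(barcode_index2 >= 0, ids[np.maximum(barcode_index2, 0)], ""),
        }
    )
    return signals, GenotypingGroundTruth(traps=traps, codebook=codebook, config=config)


def _render_table(
    config: GenotypingSimConfig,
    rng: np.random.Generator,
    occ_ids: np.ndarray,
    rendered: np.ndarray,
    rendered2: np.ndarray,
) -> pd.DataFrame:
    """Tabulated signals: background totals everywhere, blob totals on
    rendered channels. The same lognormal brightness multiplier is used
    for both clones of a double trap in a round, so rounds where their
    colours differ are genuinely ambiguous under channel dominance."""
    m, R, C = len(occ_ids), config.n_rounds, config.n_colors
    intensity = rng.normal(config.bg_mean, config.bg_sd, size=(m, R, C))
    npix = np.zeros((m, R, C), dtype=np.int64)
    mult = np.exp(rng.normal(0.0, 0.3, size=(m, R)))
    blob_area = rng.integers(2 * config.area_min_px, 4 * config.area_min_px + 1, size=(m, R, 2))
    rows = np.arange(m)
    for r in range(R):
        sym = rendered[occ_ids, r]
        has = sym >= 0
        intensity[rows[has], r, sym[has]] += config.blob_intensity_scale * mult[has, r]
        npix[rows[has], r, sym[has]] += blob_area[has, r, 0]
        sym2 = rendered2[occ_ids, r]
        has2 = sym2 >= 0
        intensity[rows[has2], r, sym2[has2]] += config.blob_intensity_scale * mult[has2, r]
        npix[rows[has2], r, sym2[has2]] += blob_area[has2, r, 1]
    df = pd.DataFrame(
        {
            "trap_id": np.repeat(occ_ids, R * C),
            "round": np.tile(np.repeat(np.arange(R), C), m),
            "channel": np.tile(np.arange(C), m * R),
            "total_intensity": intensity.ravel(),
            "n_pixels": npix.ravel(),
        }
    )
    return df


def render_trap_tiles(
    config: GenotypingSimConfig,
    rng: np.random.Generator,
    occ_ids: np.ndarray,
    rendered: np.ndarray,
    rendered2: np.ndarray,
) -> np.ndarray:
    """Render per-trap tiles: Gaussian(bg_mean, bg_sd) pixel background
    plus an isotropic 2D Gaussian blob (sigma ``blob_sigma_px``, peak
    ``blob_intensity_scale`` x lognormal(0, 0.3)) on each rendered
    channel.  The blob centre is fixed per trap (the rolling-circle
    product does not move between rounds), jittered off the tile centre.
    Pixel coordinates are 0-based, row-major."""
    m, R, C = len(occ_ids), config.n_rounds, config.n_colors
    h, w = config.trap_shape_px
    tiles = rng.normal(config.bg_mean, config.bg_sd, size=(m, R, C, h, w)).astype(np.float32)
    cy = h / 2 + rng.uniform(-2, 2, size=m)
    cx = w / 2 + rng.uniform(-2, 2, size=m)
    yy, xx = np.mgrid[0:h, 0:w]
    mult = np.exp(rng.normal(0.0, 0.3, size=(m, R)))
    for i in range(m):
        blob = np.exp(
            -((yy - cy[i]) ** 2 + (xx - cx[i]) ** 2) / (2 * config.blob_sigma_px**2)
        ).astype(np.float32)
        for r in range(R):
            peak = config.blob_intensity_scale * mult[i, r]
            for sym in (rendered[occ_ids[i], r], rendered2[occ_ids[i], r]):
                if sym >= 0:
                    tiles[i, r, sym] += peak * blob
    return tiles


def write_tiles_tiff(tiles: np.ndarray, path: str | Path) -> None:
    """Write an image-mode stack as a multi-page TIFF
    (pages ordered trap-major, then round, then channel)."""
    import tifffile

    m, R, C, h, w = tiles.shape
    tifffile.imwrite(str(path), tiles.reshape(m * R * C, h, w))


# ---------------------------------------------------------------------------
# Phenotyping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrainKinetics:
    """True maturation parameters of one strain.

    ``c`` is the total fluorescence at the medium swap, ``alpha`` the
    immature/mature ratio then, ``tau_m`` the maturation time (min) and
    ``tau_b`` the bleaching time (min) or None for a non-bleaching FP.
    """

    fp_id: str
    c: float
    alpha: float
    tau_m: float
    tau_b: float | None = None

    def __post_init__(self) -> None:
        if self.c <= 0 or self.alpha < 0 or self.tau_m <= 0:
            raise ValueError("need c > 0, alpha >= 0, tau_m > 0")
        if self.tau_b is not None and self.tau_b <= self.tau_m:
            raise ValueError(f"tau_b={self.tau_b} must exceed tau_m={self.tau_m}")


@dataclass(frozen=True)
class PhenoSimConfig:
    """Conditions of a simulated maturation (chloramphenicol-chase) run.

    Timing mirrors the study design: 60 min of steady-state imaging,
    then a swap to chloramphenicol at t = 0 and 300 min of chase, with
    fluorescence frames every 5 min (growth is simulated on the finer
    ``dt_phase`` grid).  Growth halts after the swap with an exponential
    rate decay of time constant ``growth_stop_tau_min``.
    """

    strains: tuple[StrainKinetics, ...]
    n_lineages_per_strain: int = 6
    t_pre_chl: float = 60.0
    t_post_chl: float = 300.0
    dt_fluor: float = 5.0
    dt_phase: float = 1.0
    noise_sd: float = 2.0
    bleed_fraction: float = 0.0
    doubling_time_min: float = 40.0
    growth_stop_tau_min: float = 30.0
    area0_px: float = 150.0
    bg_mean: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.strains:
            raise ValueError("need at least one strain")
        if self.dt_fluor <= 0 or self.dt_phase <= 0:
            raise ValueError("time steps must be positive")
        if abs(self.dt_fluor / self.dt_phase - round(self.dt_fluor / self.dt_phase)) > 1e-9:
            raise ValueError("dt_fluor must be an integer multiple of dt_phase")
        if not (0.0 <= self.bleed_fraction < 1.0):
            raise ValueError("bleed_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class PhenoGroundTruth:
    """``strains``: fp_id -> true kinetic parameters.
    ``lineages``: lineage_id, trap_id, fp_id mapping."""

    strains: pd.DataFrame
    lineages: pd.DataFrame
    config: PhenoSimConfig


def maturation_mean(t: np.ndarray, s: StrainKinetics) -> np.ndarray:
    """Noiseless post-swap lineage total fluorescence of strain ``s``."""
    from .maturation import double_exp_value, single_exp_value

    if s.tau_b is None:
        return single_exp_value(t, s.c, s.alpha, s.tau_m)
    return double_exp_value(t, s.c, s.alpha, s.tau_m, s.tau_b)


def gen_phenotyping(
    config: PhenoSimConfig,
    trap_ids: Mapping[str, Sequence[int]] | None = None,
) -> tuple[pd.DataFrame, PhenoGroundTruth]:
    """Simulate tracked cell observations for every strain's lineages.

    Returns a cell-observation table with columns ``time_min`` (relative
    to the chloramphenicol swap; the t = 0 frame is post-swap),
    ``trap_id, lineage_id, cell_id, parent_id, area_px,
    raw_total_intensity, surroundings_mean_density``.

    The lineage-summed fluorescence is a noisy plateau at ``c`` before
    the swap and follows the strain's maturation model after it; noise
    of sd ``noise_sd`` is added at the lineage level and apportioned to
    cells by area, so descendant sums reconstruct the lineage value
    exactly.  Cells grow exponentially and divide when they double;
    growth decays to zero after the swap.  ``bleed_fraction`` of each
    trap's fluorescence density appears in its physical neighbours'
    surroundings (traps are laid out on a line in trap-id order).
    """
    rng = np.random.default_rng(config.seed)
    n_sub = int(round(config.dt_fluor / config.dt_phase))
    times = np.arange(-config.t_pre_chl, config.t_post_chl + 1e-9, config.dt_fluor)

    lineage_rows = []
    if trap_ids is None:
        next_trap = 0
    records: list[dict] = []
    lineage_density: dict[int, np.ndarray] = {}  # trap -> density series
    per_lineage: list[tuple[str, int, StrainKinetics, list]] = []

    for s in config.strains:
        assigned = list(trap_ids[s.fp_id]) if trap_ids is not None else None
        for j in range(config.n_lineages_per_strain):
            if assigned is not None:
                trap = int(assigned[j % len(assigned)])
            else:
                trap = next_trap
                next_trap += 1
            lid = f"{s.fp_id}_lin{j}"
            lineage_rows.append({"lineage_id": lid, "trap_id": trap, "fp_id": s.fp_id})

            cells = _grow_lineage(config, rng, lid)
            # lineage fluorescence at fluor frames
            post = times >= 0
            mean = np.empty_like(times)
            mean[~post] = s.c
            mean[post] = maturation_mean(times[post], s)
            noisy = mean + (rng.normal(0.0, config.noise_sd, size=times.size) if config.noise_sd > 0 else 0.0)
            per_lineage.append((lid, trap, s, (cells, noisy)))
            total_area = np.array(
                [sum(a for (_, _, a) in frame) for frame in cells]
            )
            lineage_density[trap] = noisy / total_area

    # surroundings: bleed from adjacent traps on the 1D trap line
    all_traps = sorted(lineage_density)
    surroundings: dict[int, np.ndarray] = {}
    for trap in all_traps:
        neigh = [t for t in (trap - 1, trap + 1) if t in lineage_density]
        if neigh and config.bleed_fraction > 0:
            surroundings[trap] = config.bleed_fraction * np.mean(
                [lineage_density[t] for t in neigh], axis=0
            )
        else:
            surroundings[trap] = np.zeros(times.size)

    for lid, trap, s, (cells, noisy) in per_lineage:
        surr = surroundings[trap]
        for fi, t in enumerate(times):
            frame = cells[fi]
            total_area = sum(a for (_, _, a) in frame)
            for cell_id, parent_id, area in frame:
                share = area / total_area
                records.append(
                    {
                        "time_min": float(t),
                        "trap_id": trap,
                        "lineage_id": lid,
                        "cell_id": cell_id,
                        "parent_id": parent_id,
                        "area_px": area,
                        "raw_total_intensity": share * noisy[fi] + config.bg_mean * area,
                        "surroundings_mean_density": surr[fi],
                    }
                )

    cells_df = pd.DataFrame.from_records(records)
    strains_df = pd.DataFrame(
        [
            {"fp_id": s.fp_id, "c": s.c, "alpha": s.alpha, "tau_m": s.tau_m, "tau_b": s.tau_b}
            for s in config.strains
        ]
    )
    gt = PhenoGroundTruth(strains=strains_df, lineages=pd.DataFrame(lineage_rows), config=config)
    return cells_df, gt


def _grow_lineage(
    config: PhenoSimConfig, rng: np.random.Generator, lid: str
) -> list[list[tuple[str, str, float]]]:
    """Simulate growth/division on the dt_phase grid; return, for each
    fluorescence frame, the list of living cells as
    (cell_id, parent_id, area)."""
    n_sub = int(round(config.dt_fluor / config.dt_phase))
    times = np.arange(-config.t_pre_chl, config.t_post_chl + 1e-9, config.dt_fluor)
    g0 = np.log(2.0) / config.doubling_time_min
    # founder starts at a random cell-cycle phase
    cells = [[f"{lid}_c0", "", config.area0_px * 2 ** rng.uniform(0, 1)]]
    counter = 1
    frames: list[list[tuple[str, str, float]]] = []
    t = times[0]
    frames.append([(cid, pid, a) for cid, pid, a in cells])
    for fi in range(1, times.size):
        for _ in range(n_sub):
            rate = g0 if t < 0 else g0 * np.exp(-t / config.growth_stop_tau_min)
            factor = float(np.exp(rate * config.dt_phase))
            newcells = []
            for cid, pid, a in cells:
                a = a * factor
                if a >= 2 * config.area0_px:
                    for _ in range(2):
                        newcells.append([f"{lid}_c{counter}", cid, a / 2])
                        counter += 1
                else:
                    newcells.append([cid, pid, a])
            cells = newcells
            t += config.dt_phase
        frames.append([(cid, pid, a) for cid, pid, a in cells])
    return frames


# ---------------------------------------------------------------------------
# Amplicon reads
# ---------------------------------------------------------------------------

AMPLICON_FLANK5 = "CTCGGTACCAAATTCCAGAAAAGTCGACTT"
AMPLICON_FLANK3 = "AACTAGCGCAAGGAGACAAGAGCCTTGACG"


def gen_amplicon(
    barcodes: Sequence[BarcodeSeq],
    n_reads: int,
    read_len: int = 150,
    freqs: Sequence[float] | None = None,
    seed: int = 0,
    path: str | Path | None = None,
) -> tuple[list[str], pd.Series]:
    """Simulate amplicon reads, each embedding one barcode.

    Barcodes are sampled from ``freqs`` (uniform by default); each read
    is 5'-flank + barcode + 3'-flank, truncated or padded with the
    3' flank repeated to exactly ``read_len``.  Returns the read
    sequences and the true per-barcode counts; if ``path`` is given the
    reads are also written as FASTQ (constant quality)."""
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not barcodes:
        raise ValueError("need at least one barcode")
    bclen = len(barcodes[0].seq)
    if read_len < bclen:
        raise ValueError(f"read_len={read_len} shorter than barcode length {bclen}")
    if freqs is None:
        freqs = np.full(len(barcodes), 1.0 / len(barcodes))
    freqs = np.asarray(freqs, dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9 or (freqs < 0).any():
        raise ValueError("freqs must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(barcodes), size=n_reads, p=freqs)
    counts = pd.Series(0, index=[b.id for b in barcodes], dtype=int)
    reads = []
    filler = (AMPLICON_FLANK3 * ((read_len // len(AMPLICON_FLANK3)) + 2))
    for i in picks:
        b = barcodes[int(i)]
        seq = (AMPLICON_FLANK5 + b.seq + filler)[:read_len]
        reads.append(seq)
        counts[b.id] += 1
    if path is not None:
        with open(path, "w") as fh:
            qual = "I" * read_len
            for k, seq in enumerate(reads):
                fh.write(f"@read{k}\n{seq}\n+\n{qual}\n")
    return reads, counts
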