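"""Synthetic data generators: FRAP stacks, switching random walks, proteomes.

These generators stand in for the microscope and for downloaded proteome
databases, so every stage of the analysis can be exercised with a known
ground truth.  All generators are pure functions of (config, seed).

``generate_frap_stack`` emulates a pole-bleached line profile in a small
rod-shaped cell: a flat pre-bleach profile, a Gaussian bleach dip, forward
evolution under the same 1D reflecting-boundary diffusion model used for
fitting, and homoscedastic Gaussian read noise (Poisson shot noise is
available as a non-default option).

``simulate_switching_walk`` realises the two-state model directly: a
particle alternates between free and bound diffusion with first-order
switching, and the effective diffusion coefficient is estimated from the
end-to-end displacement variance.  At fast exchange this validates
D_eff = f_free*D_free + (1-f_free)*D_bound; at slow exchange the
displacement distribution becomes a two-Gaussian mixture.

``generate_proteome`` draws protein sequences whose charged-residue
frequencies are calibrated analytically so the expected net charge at
pH 7.5 matches a target, tags a chosen fraction of records as cytosolic
(GO:0005829) and assigns log-normal copy numbers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .charge import ProteinRecord, load_pka
from .frap import LineProfileStack, evolve_profile

__all__ = [
    "acquisition_for",
    "FrapSynthesisConfig",
    "SwitchingWalkConfig",
    "ProteomeSynthesisConfig",
    "WalkResult",
    "generate_frap_stack",
    "simulate_switching_walk",
    "generate_proteome",
    "write_proteome",
]


def acquisition_for(d: float) -> dict:
    """Acquisition settings suited to an expected diffusion speed.

    Mirrors experimental practice: short exposures and few pixels for fast
    probes, longer intervals and more frames for slow ones.  Returned dict
    holds ``n_pixels``, ``n_frames`` and ``frame_interval`` keyword
    arguments for :class:`FrapSynthesisConfig`.
    """
    if d >= 2.0:
        return dict(n_pixels=8, n_frames=50, frame_interval=0.004)
    if d >= 0.3:
        return dict(n_pixels=16, n_frames=100, frame_interval=0.02)
    return dict(n_pixels=16, n_frames=150, frame_interval=0.1)


@dataclass(frozen=True)
class FrapSynthesisConfig:
    """Parameters of a synthetic pole-bleach FRAP acquisition.

    Defaults mirror a confocal line-FRAP recording on a ~3 um bacterium:
    50 frames of 8 pixels at 4 ms intervals, a Gaussian bleach of one pixel
    width and 60% depth at the cell pole, and 2% Gaussian read noise.
    """

    d_true: float = 10.0          # um^2/s
    cell_length: float = 3.0      # um
    n_pixels: int = 8
    bleach_center: float | None = None   # um; default: the pole (first pixel)
    bleach_width: float | None = None    # um (Gaussian sigma); default: 1 px
    bleach_depth: float = 0.6     # fraction of pre-bleach intensity
    n_frames: int = 50
    frame_interval: float = 0.004  # s
    noise_sd: float = 0.02        # fraction of pre-bleach intensity
    noise_model: str = "gaussian"  # or "poisson"
    n_prebleach: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_true < 0:
            raise ValueError("d_true must be non-negative")
        if self.cell_length <= 0 or self.n_pixels < 2:
            raise ValueError("invalid cell geometry")
        if not 0.0 < self.bleach_depth <= 1.0:
            raise ValueError("bleach_depth must lie in (0, 1]")
        if self.n_frames < 2 or self.frame_interval <= 0:
            raise ValueError("invalid acquisition settings")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be 'gaussian' or 'poisson'")
        center = self.bleach_center
        if center is not None and not 0.0 <= center <= self.cell_length:
            raise ValueError("bleach_center must lie within the cell")


def generate_frap_stack(config: FrapSynthesisConfig) -> LineProfileStack:
    """Synthesize a noisy FRAP line-profile stack with known D."""
    rng = np.random.default_rng(config.seed)
    dx = config.cell_length / config.n_pixels
    positions = (np.arange(config.n_pixels) + 0.5) * dx
    width = config.bleach_width if config.bleach_width is not None else dx
    center = (
        config.bleach_center if config.bleach_center is not None
        else positions[0]
    )
    if width > config.cell_length:
        warnings.warn("bleach profile wider than the cell")

    initial = 1.0 - config.bleach_depth * np.exp(
        -((positions - center) ** 2) / (2.0 * width**2)
    )
    times = np.arange(config.n_frames) * config.frame_interval
    clean = evolve_profile(initial, config.d_true, dx, times)

    if config.noise_sd > 0:
        if config.noise_model == "gaussian":
            noisy = clean + rng.normal(0.0, config.noise_sd, clean.shape)
        else:
            # scale counts so that the SD at the pre-bleach level (1.0)
            # equals noise_sd
            counts = 1.0 / config.noise_sd**2
            noisy = rng.poisson(clean * counts) / counts
        pre = 1.0 + rng.normal(
            0.0, config.noise_sd / math.sqrt(config.n_prebleach),
            positions.shape,
        )
    else:
        noisy = clean.copy()
        pre = np.ones_like(positions)
    np.clip(noisy, 0.0, None, out=noisy)
    np.clip(pre, 1e-12, None, out=pre)
    return LineProfileStack(
        positions=positions,
        times=times,
        intensities=noisy,
        prebleach_profile=pre,
        n_prebleach=config.n_prebleach,
    )


@dataclass(frozen=True)
class SwitchingWalkConfig:
    """Two-state switching Brownian walk.

    ``k_bind`` is the free->bound rate, ``k_release`` the bound->free rate;
    the stationary free fraction is ``k_release / (k_bind + k_release)``.
    First-order switching requires ``dt * max(rate) <= 0.1``.
    """

    d_free: float = 10.0       # um^2/s
    d_bound: float = 0.04      # um^2/s
    k_bind: float = 1000.0     # 1/s
    k_release: float = 1000.0  # 1/s
    dt: float = 1e-4           # s
    n_steps: int = 10_000
    n_particles: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_bind < 0 or self.k_release < 0:
            raise ValueError("rates must be non-negative")
        if self.k_bind + self.k_release == 0:
            raise ValueError("at least one switching rate must be positive")
        if self.dt <= 0 or self.n_steps < 1 or self.n_particles < 2:
            raise ValueError("invalid simulation size")
        if self.dt * max(self.k_bind, self.k_release) > 0.1:
            raise ValueError(
                "dt * max(rate) exceeds 0.1: first-order switching would be "
                "inaccurate; reduce dt"
            )

    @property
    def stationary_f_free(self) -> float:
        return self.k_release / (self.k_bind + self.k_release)


@dataclass
class WalkResult:
    """Displacement statistics of the switching walk."""

    d_eff: float               # um^2/s, mean over particles
    d_eff_se: float            # standard error over particles
    f_free_time: float         # empirical fraction of time spent free
    f_free_time_se: float
    total_time: float          # s
    displacements: np.ndarray  # end-to-end displacement per particle, um


def simulate_switching_walk(config: SwitchingWalkConfig) -> WalkResult:
    """Simulate the switching walk and estimate D_eff from displacements.

    Each particle starts in the stationary state distribution.  The
    per-particle estimator is x_total^2 / (2 * T); its mean and standard
    error over particles are returned.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_particles
    sd_free = math.sqrt(2.0 * config.d_free * config.dt)
    sd_bound = math.sqrt(2.0 * config.d_bound * config.dt)
    p_bind = config.k_bind * config.dt
    p_release = config.k_release * config.dt

    free = rng.random(n) < config.stationary_f_free
    x = np.zeros(n)
    time_free = np.zeros(n)
    for _ in range(config.n_steps):
        x += rng.standard_normal(n) * np.where(free, sd_free, sd_bound)
        time_free += free
        u = rng.random(n)
        free = np.where(free, u >= p_bind, u < p_release)

    total_time = config.n_steps * config.dt
    d_each = x**2 / (2.0 * total_time)
    f_each = time_free / config.n_steps
    return WalkResult(
        d_eff=float(d_each.mean()),
        d_eff_se=float(d_each.std(ddof=1) / math.sqrt(n)),
        f_free_time=float(f_each.mean()),
        f_free_time_se=float(f_each.std(ddof=1) / math.sqrt(n)),
        total_time=total_time,
        displacements=x,
    )


_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class ProteomeSynthesisConfig:
    """Synthetic proteome: sizes, charge bias and cytosolic fraction."""

    n_proteins: int = 500
    length_range: tuple[int, int] = (50, 500)
    composition_bias: float = 0.0   # target mean net charge at pH 7.5
    fraction_cytoplasmic: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValueError("invalid length_range")
        if not 0.0 <= self.fraction_cytoplasmic <= 1.0:
            raise ValueError("fraction_cytoplasmic must lie in [0, 1]")


def _expected_residue_charges(ph: float = 7.5) -> dict[str, float]:
    """Expected fractional charge per residue type at the given pH (IPC
    table), used to calibrate the generator analytically."""
    pka = load_pka("ipc")
    out = {aa: 0.0 for aa in _AA}
    for aa in "HKR":
        out[aa] = 1.0 / (1.0 + 10.0 ** (ph - pka.basic[aa]))
    for aa in "DECY":
        out[aa] = -1.0 / (1.0 + 10.0 ** (pka.acidic[aa] - ph))
    out["Nterm"] = 1.0 / (1.0 + 10.0 ** (ph - pka.basic["Nterm"]))
    out["Cterm"] = -1.0 / (1.0 + 10.0 ** (pka.acidic["Cterm"] - ph))
    return out


def _calibrated_frequencies(config: ProteomeSynthesisConfig) -> np.ndarray:
    """Residue frequencies whose expected net charge hits the target bias.

    Starting from uniform frequencies, probability mass ``delta`` is moved
    onto Lys/Arg and off Asp/Glu (or the reverse), with delta solved from
    the linear relation between the frequency shift and the expected
    charge.
    """
    charges = _expected_residue_charges()
    mean_len = 0.5 * (config.length_range[0] + config.length_range[1])
    base = np.full(_AA.size, 1.0 / _AA.size)
    base_charge = mean_len * float(
        sum(base[i] * charges[a] for i, a in enumerate(_AA))
    ) + charges["Nterm"] + charges["Cterm"]
    slope = (
        charges["K"] + charges["R"] - charges["D"] - charges["E"]
    ) * mean_len
    delta = (config.composition_bias - base_charge) / slope
    max_shift = 1.0 / _AA.size - 1e-3
    delta = float(np.clip(delta, -max_shift, max_shift))
    freqs = base.copy()
    for aa in "KR":
        freqs[np.where(_AA == aa)[0][0]] += delta
    for aa in "DE":
        freqs[np.where(_AA == aa)[0][0]] -= delta
    return freqs / freqs.sum()


def generate_proteome(
    config: ProteomeSynthesisConfig,
) -> list[ProteinRecord]:
    """Draw a synthetic proteome with known charge bias and GO structure.

    Exactly ``round(fraction_cytoplasmic * n)`` records (chosen by a seeded
    permutation) carry the cytosol label GO:0005829; copy numbers are
    log-normal.
    """
    rng = np.random.default_rng(config.seed)
    freqs = _calibrated_frequencies(config)
    lo, hi = config.length_range
    n = config.n_proteins
    lengths = rng.integers(lo, hi + 1, size=n)
    n_cyto = round(config.fraction_cytoplasmic * n)
    cyto_idx = set(rng.permutation(n)[:n_cyto].tolist())

    records = []
    for i in range(n):
        seq = "".join(rng.choice(_AA, size=lengths[i], p=freqs))
        go = {"GO:0005829"} if i in cyto_idx else set()
        copy_number = float(np.round(rng.lognormal(mean=3.0, sigma=1.5)))
        records.append(
            ProteinRecord(
                id=f"SYN{i + 1:05d}",
                sequence=seq,
                copy_number=copy_number,
                go_terms=go,
            )
        )
    return records


def write_proteome(
    records: list[ProteinRecord],
    fasta_path: str | Path,
    go_path: str | Path | None = None,
    copy_path: str | Path | None = None,
    line_width: int = 60,
) -> None:
    """Serialise records to FASTA plus GO / copy-number TSV sidecars.

    Writing is plain and ordered, so a fixed seed yields byte-identical
    files.
    """
    fasta_path = Path(fasta_path)
    with fasta_path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), line_width):
                fh.write(rec.sequence[i:i + line_width] + "\n")
    if go_path is not None:
        with Path(go_path).open("w") as fh:
            fh.write("id\tgo\n")
            for rec in records:
                fh.write(f"{rec.id}\t{';'.join(sorted(rec.go_terms))}\n")
    if copy_path is not None:
        with Path(copy_path).open("w") as fh:
            fh.write("id\tcopy_number\n")
            for rec in records:
                cn = "" if rec.copy_number is None else f"{rec.copy_number:g}"
                fh.write(f"{rec.id}\t{cn}\n")
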