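"""Synthetic inputs for every pipeline stage, with known ground truth.

The generators emulate a pooled shRNA dropout screen (negative-binomial
barcode counts under a ~90% treatment kill, with planted sensitizer genes),
read-level FASTQ output, median-effect dose-response curves, fixed-ratio drug
combinations with a planted Loewe combination index, and exponential in-vivo
tumour-burden trajectories. All randomness flows through an explicit seed;
identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deconv import BarcodeLibrary, CountTable, hamming
from .synergy import dose_for_fa_params, fa_for_dose

__all__ = [
    "ScreenSimParams",
    "DoseResponseSimParams",
    "ComboSimParams",
    "InVivoSimParams",
    "make_library",
    "simulate_screen",
    "emit_reads",
    "simulate_dose_response",
    "simulate_combination",
    "simulate_invivo",
]


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass
class ScreenSimParams:
    """Conditions of the simulated dropout screen.

    ``kill_fraction`` is the baseline death probability under treatment (the
    screen drug killed about 90% of cells, hence the 0.9 default); shRNAs
    against a sensitizer gene survive treatment at an additional relative
    factor ``sensitizer_survival_multiplier`` (beta < 1 means extra killing,
    i.e. the knockdown sensitizes).
    """

    n_genes: int
    shrnas_per_gene: int = 5
    reads_per_sample: int | None = None
    nb_mean: float = 1000.0
    nb_dispersion: float = 10.0
    kill_fraction: float = 0.9
    sensitizer_genes: frozenset = field(default_factory=frozenset)
    sensitizer_survival_multiplier: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.kill_fraction < 1:
            raise ValueError("kill_fraction must be in [0, 1)")
        if not 0 < self.sensitizer_survival_multiplier <= 1:
            raise ValueError("sensitizer_survival_multiplier must be in (0, 1]")
        if self.shrnas_per_gene < 1:
            raise ValueError("shrnas_per_gene must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        self.sensitizer_genes = frozenset(self.sensitizer_genes)


@dataclass
class DoseResponseSimParams:
    """Median-effect curve parameters: fa/fu = (D/Dm)^m."""

    drug: str
    dm: float
    m: float
    doses: tuple
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dm <= 0 or self.m <= 0:
            raise ValueError("Dm and m must be positive")
        if any(d <= 0 for d in self.doses):
            raise ValueError("all doses must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class ComboSimParams:
    """Fixed-ratio combination with planted Loewe interaction.

    ``interaction`` (alpha) is the target Loewe sum d1/Dx1 + d2/Dx2 at every
    effect level in ``fa_grid``: 1 additive, < 1 synergy, > 1 antagonism. The
    ground-truth combination index of the emitted table equals alpha.
    """

    drug1: DoseResponseSimParams
    drug2: DoseResponseSimParams
    ratio: float = 1.0
    interaction: float = 1.0
    fa_grid: tuple = (0.2, 0.35, 0.5, 0.65, 0.8)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("ratio must be > 0")
        if self.interaction <= 0:
            raise ValueError("interaction must be > 0")
        if any(not 0 < fa < 1 for fa in self.fa_grid):
            raise ValueError("fa_grid values must lie in (0, 1)")


@dataclass
class InVivoSimParams:
    """Exponential growth/decay of % tumour-positive blood cells.

    Treatment starts when the labelled-cell burden reaches about 7% of white
    blood cells, hence the baseline default; groups of 4 mice follow the
    animal-study design.
    """

    growth_rates: dict  # group label -> per-day exponential rate
    n_per_group: int = 4
    baseline_pct: float = 7.0
    days: tuple = (0, 11, 24)
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.baseline_pct < 100:
            raise ValueError("baseline_pct must be in (0, 100)")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def make_library(
    n_genes: int,
    shrnas_per_gene: int = 5,
    barcode_length: int = 18,
    seed: int = 0,
    min_distance: int = 3,
    max_attempts: int = 10_000,
) -> BarcodeLibrary:
    """Random barcode library with pairwise Hamming distance >= ``min_distance``.

    Distance 3 guarantees that 1-mismatch assignment is unambiguous. Raises
    RuntimeError if a conforming barcode cannot be drawn in ``max_attempts``
    tries (library too dense for the barcode length).
    """
    if barcode_length < 8:
        raise ValueError("barcode_length must be >= 8")
    rng = np.random.default_rng(seed)
    n_bc = n_genes * shrnas_per_gene
    bases = np.array(list("ACGT"))
    barcodes: list[str] = []
    for _ in range(n_bc):
        for attempt in range(max_attempts):
            cand = "".join(bases[rng.integers(0, 4, size=barcode_length)])
            if all(hamming(cand, b) >= min_distance for b in barcodes):
                barcodes.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not draw barcode {len(barcodes) + 1}/{n_bc} with "
                f"min distance {min_distance} in {max_attempts} attempts"
            )
    genes = [f"GENE{g:04d}" for g in range(n_genes) for _ in range(shrnas_per_gene)]
    shrnas = [
        f"GENE{g:04d}_sh{s + 1}" for g in range(n_genes) for s in range(shrnas_per_gene)
    ]
    entries = pd.DataFrame({"barcode": barcodes, "shrna_id": shrnas, "gene": genes})
    return BarcodeLibrary(entries=entries)


def _negbin(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with Var = mu + mu^2/phi (phi = shape/size parameter)."""
    mean = np.asarray(mean, dtype=float)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_screen(params: ScreenSimParams, library: BarcodeLibrary):
    """Simulate control and treated barcode counts over a library.

    Control counts are NB(nb_mean, phi). Treatment multiplies the expected
    count by the survival factor s = (1 - kill_fraction) (times beta for
    shRNAs of sensitizer genes), so the expected depth-normalized
    treated:control ratio of a sensitizer shRNA is beta. If
    ``reads_per_sample`` is set, each sample is multinomially resampled to
    that fixed sequencing depth.

    Returns ``(control, treated, truth)`` where truth is a per-gene DataFrame
    with the planted sensitizer flag.
    """
    rng = np.random.default_rng(params.seed)
    genes = library.genes
    unknown = params.sensitizer_genes - set(genes)
    if unknown:
        raise ValueError(f"sensitizer genes not in library: {sorted(unknown)}")
    is_sens = genes.isin(params.sensitizer_genes).to_numpy()
    survival = np.where(
        is_sens,
        (1 - params.kill_fraction) * params.sensitizer_survival_multiplier,
        (1 - params.kill_fraction),
    )
    control_raw = _negbin(rng, np.full(len(genes), params.nb_mean), params.nb_dispersion)
    treated_raw = _negbin(rng, params.nb_mean * survival, params.nb_dispersion)

    def _depth(raw: np.ndarray) -> np.ndarray:
        if params.reads_per_sample is None or raw.sum() == 0:
            return raw
        return rng.multinomial(params.reads_per_sample, raw / raw.sum())

    control = _depth(control_raw)
    treated = _depth(treated_raw)
    idx = pd.Index(genes.index, name="shrna_id")

    def _table(values: np.ndarray, name: str) -> CountTable:
        return CountTable(
            counts=pd.DataFrame({name: values}, index=idx),
            genes=genes,
            unassigned=pd.Series({name: 0}),
        )

    truth = (
        pd.DataFrame({"gene": genes.to_numpy(), "is_sensitizer": is_sens})
        .drop_duplicates("gene")
        .set_index("gene")
    )
    return _table(control, "control"), _table(treated, "treated"), truth


def emit_reads(
    count_table: CountTable,
    library: BarcodeLibrary,
    path,
    sample: str | None = None,
    error_rate: float = 0.0,
    seed: int = 0,
) -> int:
    """Write one FASTQ read per counted barcode occurrence.

    Each read is left anchor + barcode + right anchor, with per-base
    substitution errors in the barcode at ``error_rate``. Qualities are a
    constant Q30 placeholder. Returns the number of reads written.
    """
    if not 0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    rng = np.random.default_rng(seed)
    if sample is None:
        sample = count_table.samples[0]
    left, right = library.anchors
    bc_of = dict(zip(library.entries["shrna_id"], library.entries["barcode"]))
    qual = chr(30 + 33)
    n_written = 0
    bases = "ACGT"
    with open(path, "w") as out:
        for sid, n in count_table.counts[sample].items():
            bc = bc_of[sid]
            for _ in range(int(n)):
                read_bc = bc
                if error_rate > 0:
                    errs = rng.random(len(bc)) < error_rate
                    if errs.any():
                        chars = list(read_bc)
                        for i in np.flatnonzero(errs):
                            alternatives = bases.replace(chars[i], "")
                            chars[i] = alternatives[rng.integers(0, 3)]
                        read_bc = "".join(chars)
                seq = left + read_bc + right
                out.write(f"@read{n_written}_{sid}\n{seq}\n+\n{qual * len(seq)}\n")
                n_written += 1
    return n_written


def simulate_dose_response(params: DoseResponseSimParams) -> pd.DataFrame:
    """Viability table ``drug,dose,fa`` from the median-effect model.

    Noise-free output satisfies logit(fa) = m (log D - log Dm) exactly; noise
    is additive Gaussian on the logit scale.
    """
    rng = np.random.default_rng(params.seed)
    doses = np.asarray(params.doses, dtype=float)
    logit = params.m * (np.log(doses) - np.log(params.dm))
    if params.noise_sd > 0:
        logit = logit + rng.normal(0, params.noise_sd, size=len(doses))
    fa = 1 / (1 + np.exp(-logit))
    return pd.DataFrame({"drug": params.drug, "dose": doses, "fa": fa})


def simulate_combination(params: ComboSimParams) -> pd.DataFrame:
    """Fixed-ratio combination table with ground-truth CI = ``interaction``.

    For each effect level fa in the grid, the single-agent equi-effective
    doses Dx1, Dx2 are computed from the two median-effect models and the
    combination pair (d1, d2) is placed on the ray d1:d2 = ratio so that
    d1/Dx1 + d2/Dx2 = alpha. Columns: ``d1, d2, dose` (total), ``fa``.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    rho, alpha = params.ratio, params.interaction
    for fa in params.fa_grid:
        dx1 = dose_for_fa_params(params.drug1.dm, params.drug1.m, fa)
        dx2 = dose_for_fa_params(params.drug2.dm, params.drug2.m, fa)
        d2 = alpha / (rho / dx1 + 1 / dx2)
        d1 = rho * d2
        fa_obs = fa
        if params.noise_sd > 0:
            logit = np.log(fa / (1 - fa)) + rng.normal(0, params.noise_sd)
            fa_obs = 1 / (1 + np.exp(-logit))
        rows.append({"d1": d1, "d2": d2, "dose": d1 + d2, "fa": fa_obs})
    return pd.DataFrame(rows)


def simulate_invivo(params: InVivoSimParams) -> pd.DataFrame:
    """Longitudinal burden table ``mouse,group,day,percent``.

    Noise-free group mean at day t is baseline_pct * exp(rate * t), capped at
    100%. Mouse-level noise is lognormal with unit mean and coefficient of
    variation ``noise_cv``.
    """
    rng = np.random.default_rng(params.seed)
    sigma2 = np.log1p(params.noise_cv**2)
    sigma = np.sqrt(sigma2)
    rows = []
    for group, rate in params.growth_rates.items():
        for i in range(params.n_per_group):
            mouse = f"{group}_m{i + 1}"
            for day in params.days:
                pct = params.baseline_pct * np.exp(rate * day)
                if params.noise_cv > 0:
                    pct *= rng.lognormal(-sigma2 / 2, sigma)
                rows.append(
                    {"mouse": mouse, "group": group, "day": day, "percent": min(pct, 100.0)}
                )
    return pd.DataFrame(rows)
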