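"""Seeded synthetic data with the statistical structure the pipeline assumes.

Amplification is modelled as competitive logistic growth with
amplicon-specific product inhibition: the two amplicon pools (FAM-probed,
template fraction 1-x; VIC-probed, fraction x, where x is the true
P. mexicana-derived allele fraction) share one reagent-limited carrying
capacity, and each pool additionally slows as its own product accumulates
(strand reannealing outcompetes primer binding, which acts per amplicon
species because the two alleles' products reanneal with themselves):

    N_ch(c+1) = N_ch(c) + eff_ch * N_ch(c)
                * (1 - (N_fam(c) + N_vic(c)) / K) / (1 + N_ch(c) / H)

with shared capacity K and self-inhibition scale H.  Fluorescence per
channel is baseline + gain * N_ch + iid Gaussian read noise.  The shared
capacity keeps total product bounded by K and makes pure standards behave
qualitatively differently (one channel is noise-only); the self-inhibition
term makes the majority allele reach its maximum amplification speed
earlier (so the channel inflection cycles separate, engaging the
branch-conditional ratio) and compresses the k' range towards the middle,
as observed on real dual-probe plates.  Defaults place inflection cycles
around cycle 18-30 of a 46-cycle run, as in routine TaqMan practice.

Promoter pairs are generated with one planted substitution, one planted
1 bp deletion, and one CG-enriched block that satisfies the CpG-island
criteria; the deleted base is forced to differ from both neighbours so the
optimal alignment is unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .promoter import PromoterSequence
from .sigmoid import FluorescenceCurve

__all__ = [
    "ReactionSimConfig",
    "PlateDesign",
    "SimulatedPlate",
    "simulate_reaction",
    "simulate_plate",
    "simulate_promoter_pair",
    "STANDARD_FRACTIONS",
]

# the 13 predefined plasmid-mixture fractions of the assay protocol
STANDARD_FRACTIONS = (1.0, 0.95, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05, 0.0)


def _pair(v) -> tuple[float, float]:
    if np.isscalar(v):
        return (float(v), float(v))
    a, b = v
    return (float(a), float(b))


@dataclass
class ReactionSimConfig:
    """Mechanistic parameters of one simulated dual-probe reaction.

    true_x is the VIC-probed (P. mexicana-derived) allele fraction;
    per-channel parameters accept a scalar (shared) or a (FAM, VIC) pair.
    total_template and carrying_capacity are in arbitrary copy units
    (defaults normalise the capacity to 1).
    """

    true_x: float
    total_template: float = 1e-6
    efficiency: float | tuple[float, float] = 0.9
    carrying_capacity: float = 1.0
    self_inhibition: float = 0.25
    probe_gain: float | tuple[float, float] = 3.0
    baseline: float | tuple[float, float] = 0.1
    noise_sd: float = 0.005
    n_cycles: int = 46
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_x <= 1.0:
            raise ValueError("true_x must lie in [0, 1]")
        if self.total_template <= 0 or self.carrying_capacity <= 0:
            raise ValueError("template and carrying capacity must be positive")
        if self.self_inhibition <= 0:
            raise ValueError("self_inhibition scale must be positive")
        for eff in _pair(self.efficiency):
            if not 0.0 < eff <= 1.0:
                raise ValueError("efficiency must lie in (0, 1]")
        for g in _pair(self.probe_gain):
            if g <= 0:
                raise ValueError("probe gain must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_cycles < 8:
            raise ValueError("need at least 8 cycles")


def simulate_reaction(config: ReactionSimConfig,
                      well_id: str = "W1") -> tuple[FluorescenceCurve, FluorescenceCurve]:
    """Simulate one reaction; returns the (FAM, VIC) fluorescence curves."""
    rng = np.random.default_rng(config.seed)
    eff = np.array(_pair(config.efficiency))
    gain = np.array(_pair(config.probe_gain))
    base = np.array(_pair(config.baseline))
    K = config.carrying_capacity
    n = config.n_cycles
    # row 0 = FAM (latipinna-derived, fraction 1-x), row 1 = VIC (mexicana, x)
    N = np.zeros((2, n + 1))
    N[:, 0] = config.total_template * np.array([1.0 - config.true_x, config.true_x])
    H = config.self_inhibition
    for c in range(n):
        total = N[:, c].sum()
        N[:, c + 1] = N[:, c] + (eff * N[:, c] * (1.0 - total / K)
                                 / (1.0 + N[:, c] / H))
    fluor = base[:, None] + gain[:, None] * N[:, 1:]
    if config.noise_sd > 0:
        fluor = fluor + rng.normal(0.0, config.noise_sd, size=fluor.shape)
    cycles = np.arange(1, n + 1)
    fam = FluorescenceCurve(well_id, "FAM", cycles, fluor[0])
    vic = FluorescenceCurve(well_id, "VIC", cycles, fluor[1])
    return fam, vic


@dataclass
class PlateDesign:
    """Layout of a simulated plate: standards, replicates and unknowns."""

    standard_fractions: Sequence[float] = STANDARD_FRACTIONS
    replicates: int = 3
    unknowns: Sequence[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for x in self.standard_fractions:
            if not 0.0 <= x <= 1.0:
                raise ValueError("standard fractions must lie in [0, 1]")
        for _, _, x in self.unknowns:
            if not 0.0 <= x <= 1.0:
                raise ValueError("unknown true fractions must lie in [0, 1]")


@dataclass
class SimulatedPlate:
    curves: dict
    fluorescence: pd.DataFrame
    sample_sheet: pd.DataFrame
    true_fractions: dict

    def sample_entries(self) -> list:
        """Sample-sheet rows as validated SampleSheetEntry objects."""
        from .io import SampleSheetEntry
        entries = []
        for row in self.sample_sheet.itertuples():
            x = row.x_true
            entries.append(SampleSheetEntry(
                well=row.well, role=row.role,
                x_true=(float(x) if x != "" and x is not None else None),
                sample_id=(row.sample_id or None),
                tissue=(row.tissue or None),
                replicate=int(row.replicate),
            ))
        return entries

    def write_csvs(self, outdir: str | Path) -> tuple[Path, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fluor_path = outdir / "fluorescence.csv"
        sheet_path = outdir / "sample_sheet.csv"
        self.fluorescence.to_csv(fluor_path, index=False)
        self.sample_sheet.to_csv(sheet_path, index=False)
        return fluor_path, sheet_path


def _well_seed(master_seed: int, well_index: int) -> int:
    # fixed derivation: SeedSequence entropy (master, index) -> one 32-bit word
    return int(np.random.SeedSequence([int(master_seed), int(well_index)]).generate_state(1)[0])


def simulate_plate(design: PlateDesign, base_config: ReactionSimConfig | None = None,
                   seed: int = 0) -> SimulatedPlate:
    """Simulate every standard and unknown well of a plate design.

    Per-well seeds derive deterministically from (seed, well index), so the
    plate is bit-reproducible and individual wells are independent.
    """
    if base_config is None:
        base_config = ReactionSimConfig(true_x=0.5)
    rows = []
    sheet = []
    curves: dict = {}
    true_fractions: dict = {}
    well_index = 0
    layout: list[tuple[str, dict, float]] = []
    for i, x in enumerate(design.standard_fractions):
        for r in range(1, design.replicates + 1):
            well = f"S{i:02d}R{r}"
            layout.append((well, {"role": "STANDARD", "x_true": x, "sample_id": "",
                                  "tissue": "", "replicate": r}, x))
    for j, (sample_id, tissue, x) in enumerate(design.unknowns):
        for r in range(1, design.replicates + 1):
            well = f"U{j:02d}R{r}"
            layout.append((well, {"role": "UNKNOWN", "x_true": "", "sample_id": sample_id,
                                  "tissue": tissue, "replicate": r}, x))
    for well, meta, x in layout:
        cfg = ReactionSimConfig(
            true_x=x,
            total_template=base_config.total_template,
            efficiency=base_config.efficiency,
            carrying_capacity=base_config.carrying_capacity,
            self_inhibition=base_config.self_inhibition,
            probe_gain=base_config.probe_gain,
            baseline=base_config.baseline,
            noise_sd=base_config.noise_sd,
            n_cycles=base_config.n_cycles,
            seed=_well_seed(seed, well_index),
        )
        fam, vic = simulate_reaction(cfg, well_id=well)
        curves[(well, "FAM")] = fam
        curves[(well, "VIC")] = vic
        true_fractions[well] = x
        for curve in (fam, vic):
            for cyc, f in zip(curve.cycles, curve.fluorescence):
                rows.append((well, int(cyc), curve.channel, float(f)))
        sheet.append({"well": well, **meta})
        well_index += 1
    fluor_df = pd.DataFrame(rows, columns=["well", "cycle", "channel", "fluorescence"])
    sheet_df = pd.DataFrame(sheet, columns=["well", "role", "x_true",
                                            "sample_id", "tissue", "replicate"])
    return SimulatedPlate(curves=curves, fluorescence=fluor_df,
                          sample_sheet=sheet_df, true_fractions=true_fractions)


# tissue-level study conditions: mean P. mexicana-derived fraction and
# between-fish biological sd, as observed in the original ar-alpha study
TISSUE_MEANS = {"ovary": 0.770, "brain": 0.462, "gill": 0.407}
TISSUE_SDS = {"ovary": 0.02, "brain": 0.04, "gill": 0.09}


def ase_study_design(seed: int = 0, n_samples: int = 4,
                     tissue_means: dict[str, float] | None = None,
                     tissue_sds: dict[str, float] | None = None,
                     replicates: int = 3) -> PlateDesign:
    """Plate design emulating the ASE study: per-fish biological variation.

    Each biological sample's true allele fraction is drawn from
    Normal(tissue mean, tissue sd), clipped to [0, 1]; the defaults are the
    study's observed per-tissue means and between-fish standard deviations.
    Technical (read-noise) variation is added later by the reaction
    simulator; this function models only fish-to-fish variation.
    """
    means = tissue_means or TISSUE_MEANS
    sds = tissue_sds or TISSUE_SDS
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 815]))
    unknowns = []
    for tissue in means:
        draws = np.clip(rng.normal(means[tissue], sds[tissue], size=n_samples), 0.0, 1.0)
        for i, x in enumerate(draws, start=1):
            unknowns.append((f"fish{i}", tissue, float(x)))
    return PlateDesign(replicates=replicates, unknowns=unknowns)


def gdna_study_design(n_samples: int = 6, replicates: int = 3) -> PlateDesign:
    """gDNA assessment design: heterozygous genomes, true fraction exactly 0.5."""
    unknowns = [(f"fish{i}", "gDNA", 0.5) for i in range(1, n_samples + 1)]
    return PlateDesign(replicates=replicates, unknowns=unknowns)


_BASES = np.array(list("ACGT"))


def _draw(rng: np.random.Generator, n: int, p: Sequence[float]) -> np.ndarray:
    return rng.choice(_BASES, size=n, p=np.asarray(p) / np.sum(p))


def simulate_promoter_pair(length: int = 670, snp_pos: int | None = 77,
                           indel_pos: int | None = 231,
                           gc_background: float = 0.3,
                           island_span: tuple[int, int] | None = (200, 520),
                           seed: int = 7) -> tuple[PromoterSequence, PromoterSequence]:
    """Generate a promoter-allele pair with planted SNP, deletion and CpG island.

    Sequence A is drawn from an AT-rich background (GC fraction
    ``gc_background``) with a CG-enriched block over ``island_span``
    (1-based inclusive); sequence B equals A with a substitution at
    ``snp_pos`` and a 1 bp deletion at ``indel_pos`` (both 1-based on A).
    Positions of None disable the corresponding feature.
    """
    if snp_pos is not None and indel_pos is not None and snp_pos == indel_pos:
        raise ValueError("snp_pos and indel_pos must differ")
    for name, pos in (("snp_pos", snp_pos), ("indel_pos", indel_pos)):
        if pos is not None and not 1 <= pos <= length:
            raise ValueError(f"{name} outside sequence of length {length}")
    rng = np.random.default_rng(seed)
    gcb = gc_background / 2.0
    atb = (1.0 - gc_background) / 2.0
    seq = _draw(rng, length, [atb, gcb, gcb, atb])  # order A C G T
    if island_span is not None:
        lo, hi = island_span
        if not (1 <= lo <= hi <= length):
            raise ValueError("island_span outside sequence")
        # iid CG-rich block: GC ~0.8, O/E(CpG) ~1 >> thresholds
        seq[lo - 1:hi] = _draw(rng, hi - lo + 1, [0.1, 0.4, 0.4, 0.1])
    if indel_pos is not None:
        # force the deleted base to differ from both neighbours so the
        # alignment gap placement is unambiguous
        neighbours = set()
        if indel_pos >= 2:
            neighbours.add(seq[indel_pos - 2])
        if indel_pos <= length - 1:
            neighbours.add(seq[indel_pos])
        choices = [b for b in "ACGT" if b not in neighbours]
        seq[indel_pos - 1] = rng.choice(np.array(choices))
    seq_a = "".join(seq)
    b_list = list(seq_a)
    if snp_pos is not None:
        old = b_list[snp_pos - 1]
        b_list[snp_pos - 1] = rng.choice(np.array([b for b in "ACGT" if b != old]))
    if indel_pos is not None:
        del b_list[indel_pos - 1]
    seq_b = "".join(b_list)
    a = PromoterSequence(id="alleleA", residues=seq_a, species_or_allele="ancestor A")
    b = PromoterSequence(id="alleleB", residues=seq_b, species_or_allele="ancestor B")
    return a, b
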