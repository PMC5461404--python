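"""Proteome Pro-Pro motif census and the ribosome-interrogation budget.

Connects the kinetic picture to cell-scale arithmetic: the copy-weighted
frequency of Pro-Pro motifs in the expressed proteome, the number of such
motifs present in a single-cell transcriptome, the molar concentration of
translating ribosomes, the effective bimolecular binding rate constant
implied by the measured search time tau_free, and the total rate at which
the cell's EF-P pool samples ("interrogates") ribosomal E sites.

Includes a synthetic proteome generator with a controllable motif fraction
so the whole chain runs without external abundance tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ProteomeRecord",
    "CensusParams",
    "CensusReport",
    "count_pro_pro",
    "motif_fraction",
    "motifs_per_cell",
    "molarity",
    "bimolecular_rate",
    "interrogation_budget",
    "synthetic_proteome",
    "read_proteome_table",
]

AVOGADRO = 6.02214076e23
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return float(np.round(x, -int(np.floor(np.log10(abs(x)))) + (sig - 1)))


@dataclass(frozen=True)
class ProteomeRecord:
    """One protein: length (codons), Pro-Pro duet count, copies per cell."""

    gene_id: str
    length: int
    pro_pro_count: int
    copies_per_cell: float
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.pro_pro_count < 0 or self.copies_per_cell < 0:
            raise ValueError("counts must be non-negative")
        if self.pro_pro_count > self.length - 1:
            raise ValueError("pro_pro_count cannot exceed length - 1")


def count_pro_pro(sequence: str) -> Tuple[int, int]:
    """Count overlapping Pro-Pro duets and Pro-Pro-Pro triplets.

    Overlapping convention: "PPPP" contains 3 duets and 2 triplets.
    Raises on any letter outside the 20-amino-acid alphabet, naming the
    position.
    """
    seq = sequence.upper()
    for i, ch in enumerate(seq):
        if ch not in AMINO_ACIDS:
            raise ValueError(f"invalid amino acid {ch!r} at position {i}")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("P")
    duets = int(np.sum(arr[:-1] & arr[1:])) if len(seq) >= 2 else 0
    triplets = (
        int(np.sum(arr[:-2] & arr[1:-1] & arr[2:])) if len(seq) >= 3 else 0
    )
    return duets, triplets


def motif_fraction(records: Sequence[ProteomeRecord]) -> float:
    """Copy-weighted Pro-Pro frequency per translated codon.

    sum(pro_pro_count * copies) / sum(length * copies): the fraction of
    codon positions in the expressed proteome that begin a Pro-Pro motif.
    """
    if not records:
        raise ValueError("empty proteome")
    num = sum(r.pro_pro_count * r.copies_per_cell for r in records)
    den = sum(r.length * r.copies_per_cell for r in records)
    if den <= 0:
        raise ValueError("copy-weighted total length must be positive")
    return num / den


def motifs_per_cell(
    fraction: float, mrna_copies: float, codons_per_mrna: float
) -> Tuple[float, float]:
    """Expected Pro-Pro motifs in one cell's transcriptome.

    Product of the motif fraction, the mRNA copy number, and the mean coding
    length; returned both unrounded and rounded to two significant figures.
    """
    if mrna_copies <= 0 or codons_per_mrna <= 0:
        raise ValueError("inputs must be positive")
    value = fraction * mrna_copies * codons_per_mrna
    return value, round_sig(value, 2)


def molarity(copies: float, volume_um3: float) -> float:
    """Concentration (mol/L) of ``copies`` molecules in ``volume_um3`` µm³."""
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    return copies / (volume_um3 * 1e-15 * AVOGADRO)


def bimolecular_rate(
    tau_free_ms: float, concentration: float, k_diff: float = 4e8
) -> Tuple[float, float]:
    """Effective bimolecular binding rate constant and diffusion-limit ratio.

    k_bimol = (1/tau_free) / [target], with tau_free in ms converted to
    seconds.  Returns (k_bimol in 1/(M s), k_diff / k_bimol).
    """
    if tau_free_ms <= 0 or concentration <= 0:
        raise ValueError("inputs must be positive")
    k_bimol = (1000.0 / tau_free_ms) / concentration
    return k_bimol, k_diff / k_bimol


@dataclass(frozen=True)
class CensusParams:
    """Inputs to the interrogation budget (cell-scale literature numbers)."""

    mrna_copies_per_cell: float = 2000.0
    codons_per_mrna: float = 260.0
    total_30S: float = 50_000.0
    translating_fraction: float = 0.8
    cell_volume_um3: float = 3.0
    translation_rate_aa_s: float = 20.0
    efp_copies_low: float = 5_000.0
    efp_copies_high: float = 20_000.0
    f_slow: float = 0.30
    tau_free_ms: float = 16.0
    tau_bound_ms: float = 7.0
    k_diff: float = 4e8

    def __post_init__(self) -> None:
        if self.translating_fraction > 1:
            raise ValueError("translating_fraction must be <= 1")
        for name in (
            "mrna_copies_per_cell",
            "codons_per_mrna",
            "total_30S",
            "translating_fraction",
            "cell_volume_um3",
            "translation_rate_aa_s",
            "f_slow",
            "tau_free_ms",
            "tau_bound_ms",
            "k_diff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class CensusReport:
    """Derived cell-scale quantities (low/high track the EF-P copy range)."""

    motif_fraction: float
    motifs_per_cell: float
    translating_ribosomes: float
    ribosome_concentration: float
    k_bimol: float
    k_diff_ratio: float
    cycle_time_ms: float
    cycles_per_copy_per_s: float
    interrogations_per_s_low: float
    interrogations_per_s_high: float
    per_ribosome_visits_per_s_low: float
    per_ribosome_visits_per_s_high: float
    elongation_cycles_per_s: float
    elongation_cycle_upper_ms: float
    snapshot_complexes_low: float
    snapshot_complexes_high: float

    def __post_init__(self) -> None:
        for lo, hi in (
            (self.interrogations_per_s_low, self.interrogations_per_s_high),
            (self.per_ribosome_visits_per_s_low, self.per_ribosome_visits_per_s_high),
            (self.snapshot_complexes_low, self.snapshot_complexes_high),
        ):
            if lo > hi:
                raise ValueError("low exceeds high in a ranged field")


def interrogation_budget(
    params: CensusParams, fraction: Optional[float] = None
) -> CensusReport:
    """Full arithmetic chain from kinetic and copy-number inputs.

    One binding/search cycle lasts tau_free + tau_bound; each EF-P copy
    performs 1000/cycle_time cycles (E-site interrogations) per second, so
    the cellwide interrogation rate scales linearly with the EF-P copy
    number.  ``fraction`` supplies a measured motif fraction (e.g. from
    :func:`motif_fraction`); default 5.3e-4.
    """
    frac = 5.3e-4 if fraction is None else fraction
    cycle = params.tau_free_ms + params.tau_bound_ms
    cycles_per_s = 1000.0 / cycle
    translating = params.total_30S * params.translating_fraction
    conc = molarity(translating, params.cell_volume_um3)
    k_bimol, ratio = bimolecular_rate(params.tau_free_ms, conc, params.k_diff)
    motifs, _ = motifs_per_cell(frac, params.mrna_copies_per_cell, params.codons_per_mrna)
    return CensusReport(
        motif_fraction=frac,
        motifs_per_cell=motifs,
        translating_ribosomes=translating,
        ribosome_concentration=conc,
        k_bimol=k_bimol,
        k_diff_ratio=ratio,
        cycle_time_ms=cycle,
        cycles_per_copy_per_s=cycles_per_s,
        interrogations_per_s_low=params.efp_copies_low * cycles_per_s,
        interrogations_per_s_high=params.efp_copies_high * cycles_per_s,
        per_ribosome_visits_per_s_low=params.efp_copies_low * cycles_per_s / translating,
        per_ribosome_visits_per_s_high=params.efp_copies_high
        * cycles_per_s
        / translating,
        elongation_cycles_per_s=translating * params.translation_rate_aa_s,
        elongation_cycle_upper_ms=1000.0 / params.translation_rate_aa_s,
        snapshot_complexes_low=params.f_slow * params.efp_copies_low,
        snapshot_complexes_high=params.f_slow * params.efp_copies_high,
    )


def _random_sequence(
    length: int, n_duets: int, rng: np.random.Generator
) -> str:
    """Random sequence over the non-Pro alphabet with exactly n_duets
    isolated Pro-Pro duets (non-adjacent, so no accidental triplets)."""
    letters = np.array(list(AMINO_ACIDS.replace("P", "")))
    seq = rng.choice(letters, size=length)
    if n_duets:
        # choose duet start positions at least 3 apart so duets stay isolated
        max_duets = (length + 1) // 3
        if n_duets > max_duets:
            raise ValueError("cannot place that many isolated duets")
        # sample without adjacency by spacing trick
        slots = length + 2 - 3 * n_duets
        starts = np.sort(rng.choice(slots, size=n_duets, replace=False))
        starts = starts + 3 * np.arange(n_duets)
        for s in starts:
            seq[s] = "P"
            seq[s + 1] = "P"
    return "".join(seq)


def synthetic_proteome(
    n_genes: int = 1611,
    mean_length: float = 260.0,
    target_motif_fraction: float = 5.3e-4,
    copy_dist: str = "lognormal",
    seed: int = 0,
    copy_total: float = 4.8e6,
) -> List[ProteomeRecord]:
    """Generate a synthetic proteome table with a tuned motif fraction.

    Gene lengths are drawn from a gamma distribution with the given mean,
    copy numbers from a heavy-tailed lognormal rescaled to ``copy_total``
    (mimicking measured abundance tables).  Pro-Pro duets are first drawn
    binomially at the target rate per gene, then a correction pass on the
    lowest-copy genes brings the copy-weighted fraction within 10% of the
    target.  Deterministic given ``seed``.
    """
    if target_motif_fraction < 0:
        raise ValueError("target fraction must be >= 0")
    rng = np.random.default_rng(seed)
    lengths = np.maximum(
        30, rng.gamma(shape=3.0, scale=mean_length / 3.0, size=n_genes)
    ).astype(int)
    if copy_dist == "lognormal":
        copies = rng.lognormal(mean=0.0, sigma=1.6, size=n_genes)
    elif copy_dist == "uniform":
        copies = np.ones(n_genes)
    else:
        raise ValueError(f"unknown copy_dist {copy_dist!r}")
    copies = np.maximum(20, copies / copies.sum() * copy_total).astype(int)

    max_duets = (lengths + 1) // 3
    if target_motif_fraction == 0:
        duets = np.zeros(n_genes, dtype=int)
    else:
        denom = float(np.sum(lengths * copies))
        target_num = target_motif_fraction * denom
        if target_motif_fraction >= float(np.sum(max_duets * copies)) / denom:
            raise ValueError("target motif fraction not achievable")
        duets = rng.binomial(lengths - 1, target_motif_fraction)
        duets = np.minimum(duets, max_duets)
        # correction pass: adjust low-copy genes until within 5% of target
        num = float(np.sum(duets * copies))
        order = np.argsort(copies, kind="stable")
        tol = 0.05 * target_num
        for idx in np.tile(order, 50):
            err = num - target_num
            if abs(err) <= tol:
                break
            if err < 0 and duets[idx] < max_duets[idx] and copies[idx] <= -err:
                duets[idx] += 1
                num += copies[idx]
            elif err > 0 and duets[idx] > 0 and copies[idx] <= err:
                duets[idx] -= 1
                num -= copies[idx]
        else:
            raise RuntimeError("motif-fraction tuning failed to converge")

    records = []
    for i in range(n_genes):
        seq = _random_sequence(int(lengths[i]), int(duets[i]), rng)
        d, _ = count_pro_pro(seq)
        records.append(
            ProteomeRecord(
                gene_id=f"g{i:05d}",
                length=int(lengths[i]),
                pro_pro_count=d,
                copies_per_cell=float(copies[i]),
                sequence=seq,
            )
        )
    achieved = motif_fraction(records)
    if target_motif_fraction > 0 and not (
        0.9 * target_motif_fraction <= achieved <= 1.1 * target_motif_fraction
    ):
        raise RuntimeError(
            f"achieved fraction {achieved:.3g} outside 10% of target"
        )
    return records


def read_proteome_table(path) -> List[ProteomeRecord]:
    """Read a proteome CSV (gene_id, length, pro_pro_count OR sequence,
    copies_per_cell); motif counts are derived from sequences if present."""
    import pandas as pd

    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        if "sequence" in df.columns and isinstance(row.get("sequence"), str):
            seq = row["sequence"]
            duets, _ = count_pro_pro(seq)
            length = int(row["length"]) if "length" in df.columns else len(seq)
        else:
            seq = None
            duets = int(row["pro_pro_count"])
            length = int(row["length"])
        records.append(
            ProteomeRecord(
                gene_id=str(row["gene_id"]),
                length=length,
                pro_pro_count=duets,
                copies_per_cell=float(row["copies_per_cell"]),
                sequence=seq,
            )
        )
    return records
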