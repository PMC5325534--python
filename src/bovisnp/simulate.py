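"""Synthetic variant panels with the breed x age x replicate structure of
the study design, plus genotype tables and mapping summaries, all with
ground truth for plant-and-recover testing.

The generator emulates the statistical shape of per-sample RNA-seq
variant calls, not the reads: each site gets a latent class (breed
private / shared by a breed pair / shared by all / multi-allele error /
unassembled-reference 'de novo') and a latent zygosity (fixed alternate
or heterozygous); every sample of a carrier breed then draws a read
depth from a negative binomial and an alternate depth from a binomial
whose success probability reflects zygosity and the sequencing error
rate.  Error sites emit two records with distinct alternate alleles at
one position; de-novo sites carry reference base 'N'.  Everything is a
pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    AGES,
    Breed,
    FlagstatProfile,
    GeneLocus,
    GenotypeTable,
    SampleMeta,
    ValidationError,
    VariantRecord,
    full_panel,
)

_BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Panel-level simulation parameters.

    The design block (3 breeds x ages {6, 9, 12} x 2 replicates) is the
    study's; the site-class fractions and the negative-binomial coverage
    model (mean 30, dispersion 5 — a standard bulk RNA-seq shape) are the
    generator's own defaults.
    """

    seed: int
    n_sites: int = 5_000
    breed_private_fraction: float = 0.30
    shared_fraction: float = 0.40        # shared by all three breeds
    fixed_alt_fraction: float = 0.60     # latent hom-alt sites
    het_fraction: float = 0.40
    error_site_fraction: float = 0.02    # multi-alt positions
    n_site_fraction: float = 0.01        # ref = 'N' ("de novo")
    indel_fraction: float = 0.02         # of ordinary sites, emitted as indels
    depth_mean: float = 30.0
    depth_dispersion: float = 5.0
    seq_error_rate: float = 0.005
    ages: tuple = AGES
    replicates_per_cell: int = 2

    def __post_init__(self) -> None:
        fractions = {
            "breed_private_fraction": self.breed_private_fraction,
            "shared_fraction": self.shared_fraction,
            "fixed_alt_fraction": self.fixed_alt_fraction,
            "het_fraction": self.het_fraction,
            "error_site_fraction": self.error_site_fraction,
            "n_site_fraction": self.n_site_fraction,
            "indel_fraction": self.indel_fraction,
        }
        for name, v in fractions.items():
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.breed_private_fraction + self.shared_fraction > 1:
            raise ValidationError("private + shared fractions exceed 1")
        if abs(self.fixed_alt_fraction + self.het_fraction - 1) > 1e-9:
            raise ValidationError("fixed_alt_fraction + het_fraction must be 1")
        if self.error_site_fraction + self.n_site_fraction > 1:
            raise ValidationError("error + de-novo fractions exceed 1")
        if self.n_sites < 1:
            raise ValidationError("n_sites must be >= 1")
        if self.replicates_per_cell != 2:
            raise ValidationError("the design uses 2 replicates per cell")
        if not 0 <= self.seq_error_rate < 0.5:
            raise ValidationError("seq_error_rate must lie in [0, 0.5)")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValidationError("depth parameters must be positive")


def _draw_depth(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    k, m = cfg.depth_dispersion, cfg.depth_mean
    return max(1, int(rng.negative_binomial(k, k / (k + m))))


def simulate_variant_panel(config: SimulationConfig
                           ) -> tuple[dict[SampleMeta, list[VariantRecord]],
                                      pd.DataFrame]:
    """Generate per-sample call lists plus the site-level truth table.

    Truth columns: site_id, chrom, pos, ref, alt, alt2 (error sites
    only), label in {private, pairwise, shared, error, de_novo},
    zygosity in {fixed, het}, variant_class, breeds (comma-joined
    carrier breeds).
    """
    rng = np.random.default_rng(config.seed)
    panel = full_panel()
    breeds = list(Breed)

    # unique genomic positions
    positions: set[tuple[str, int]] = set()
    sites: list[tuple[str, int]] = []
    while len(sites) < config.n_sites:
        chrom = str(int(rng.integers(1, 30)))
        pos = int(rng.integers(1, 10**8))
        if (chrom, pos) not in positions:
            positions.add((chrom, pos))
            sites.append((chrom, pos))

    # latent classes
    u = rng.random(config.n_sites)
    labels = np.full(config.n_sites, "shared", dtype=object)
    e, nn = config.error_site_fraction, config.n_site_fraction
    pr, sh = config.breed_private_fraction, config.shared_fraction
    labels[u < e] = "error"
    labels[(u >= e) & (u < e + nn)] = "de_novo"
    rest = u >= e + nn
    v = rng.random(config.n_sites)
    labels[rest & (v < pr)] = "private"
    labels[rest & (v >= pr) & (v >= pr + sh)] = "pairwise"
    # rest with pr <= v < pr+sh stay "shared"
    labels[rest & (v >= pr) & (v < pr + sh)] = "shared"

    zygosity = np.where(rng.random(config.n_sites) < config.fixed_alt_fraction,
                        "fixed", "het")
    is_indel = rng.random(config.n_sites) < config.indel_fraction

    per_sample: dict[SampleMeta, list[VariantRecord]] = {s: [] for s in panel}
    truth_rows = []
    for i, (chrom, pos) in enumerate(sites):
        label = labels[i]
        if label == "de_novo":
            ref = "N"
        else:
            ref = _BASES[rng.integers(4)]
        alt_choices = [b for b in _BASES if b != ref]
        alt = alt_choices[rng.integers(len(alt_choices))]
        alt2 = None
        if label == "error":
            others = [b for b in alt_choices if b != alt]
            alt2 = others[rng.integers(len(others))]
        variant_class = "SNP"
        if label in ("private", "pairwise", "shared") and is_indel[i]:
            variant_class = "INDEL"
            ins = "".join(_BASES[rng.integers(4)]
                          for _ in range(int(rng.integers(1, 4))))
            alt = "+" + ins
        if label == "private":
            carriers = [breeds[rng.integers(3)]]
        elif label == "pairwise":
            drop = rng.integers(3)
            carriers = [b for j, b in enumerate(breeds) if j != drop]
        else:
            carriers = breeds
        q = (1 - config.seq_error_rate) if zygosity[i] == "fixed" else 0.5
        for sample in panel:
            if sample.breed not in carriers:
                continue
            for allele in ([alt] if alt2 is None else [alt, alt2]):
                depth = _draw_depth(rng, config)
                alt_depth = int(rng.binomial(depth, q))
                if alt_depth == 0:
                    continue
                per_sample[sample].append(VariantRecord(
                    chrom=chrom, pos=pos, ref_base=ref, alt_allele=allele,
                    total_depth=depth, alt_depth=alt_depth, sample=sample))
        truth_rows.append({
            "site_id": i, "chrom": chrom, "pos": pos, "ref": ref,
            "alt": alt, "alt2": alt2 if alt2 is not None else "",
            "label": label, "zygosity": zygosity[i],
            "variant_class": variant_class,
            "breeds": ",".join(b.value for b in carriers),
        })
    truth = pd.DataFrame(truth_rows)
    return per_sample, truth


def make_loci_over_sites(truth: pd.DataFrame, site_ids: Sequence[int],
                         flank: int = 50,
                         symbol_prefix: str = "LOC") -> list[GeneLocus]:
    """One locus per chosen truth site, a small interval around its
    position; convenient for plant-and-recover locus classification."""
    loci = []
    for sid in site_ids:
        row = truth.loc[truth.site_id == sid].iloc[0]
        loci.append(GeneLocus(
            symbol=f"{symbol_prefix}{int(sid):05d}", chrom=str(row.chrom),
            start=max(1, int(row.pos) - flank), end=int(row.pos) + flank))
    return loci


def simulate_genotype_table(marker_id: str,
                            allele_freqs: dict[Breed, float],
                            n_per_breed: dict[Breed, int],
                            inbreeding: float = 0.0,
                            seed: int = 0,
                            allele_ref: str = "C",
                            allele_alt: str = "T") -> GenotypeTable:
    """Draw per-breed genotypes under allele frequency p and inbreeding
    coefficient F: P(RR, RA, AA) = (p^2 + Fpq, 2pq(1-F), q^2 + Fpq)."""
    rng = np.random.default_rng(seed)
    table = GenotypeTable(marker_id=marker_id, allele_ref=allele_ref,
                          allele_alt=allele_alt)
    for breed, p in allele_freqs.items():
        if not 0 <= p <= 1:
            raise ValidationError(f"allele frequency must lie in [0, 1], got {p}")
        q = 1 - p
        probs = (p * p + inbreeding * p * q,
                 2 * p * q * (1 - inbreeding),
                 q * q + inbreeding * p * q)
        if any(pr < -1e-12 for pr in probs):
            raise ValidationError(
                f"inbreeding F={inbreeding} gives a negative genotype "
                f"probability at p={p}")
        probs = np.clip(probs, 0, None)
        probs = probs / probs.sum()
        draws = rng.choice(3, size=n_per_breed[breed], p=probs)
        for j, g in enumerate(draws):
            table.calls.append((f"{breed.value}_{j:03d}", breed,
                                ("RR", "RA", "AA")[g]))
    return table


def simulate_flagstat(label: str, total: int,
                      mapped_rate: float = 0.98,
                      properly_paired_rate: float = 0.82,
                      singleton_rate: float = 0.01,
                      diff_chr_rate: float = 0.04,
                      mapq5_fraction: float = 0.5,
                      seed: int = 0) -> FlagstatProfile:
    """A mapping summary whose ten counters satisfy every structural
    invariant by construction; rates are jittered slightly so repeated
    draws differ, reproducibly from the seed."""
    for name, r in (("mapped_rate", mapped_rate),
                    ("properly_paired_rate", properly_paired_rate),
                    ("singleton_rate", singleton_rate),
                    ("diff_chr_rate", diff_chr_rate),
                    ("mapq5_fraction", mapq5_fraction)):
        if not 0 <= r <= 1:
            raise ValidationError(f"{name} must lie in [0, 1], got {r}")
    if total < 0:
        raise ValidationError("total must be non-negative")
    rng = np.random.default_rng(seed)

    def jitter(rate: float) -> float:
        # saturated rates (0 or 1) stay exact so degenerate profiles are
        # constructible; interior rates get a small reproducible wobble
        if rate in (0.0, 1.0):
            return rate
        return float(np.clip(rate * (1 + 0.02 * rng.standard_normal()), 0, 1))

    read1 = total // 2
    read2 = total - read1
    mapped = int(total * jitter(mapped_rate))
    properly = int(mapped * jitter(properly_paired_rate))
    singletons = min(int(mapped * jitter(singleton_rate)), mapped)
    itself = mapped - singletons
    diff_chr = int(itself * jitter(diff_chr_rate))
    mapq5 = int(diff_chr * jitter(mapq5_fraction))
    return FlagstatProfile(
        label=label, total=total, mapped=mapped,
        paired_in_sequencing=total, read1=read1, read2=read2,
        properly_paired=properly, itself_and_mate_mapped=itself,
        singletons=singletons, mate_diff_chr=diff_chr,
        mate_diff_chr_mapq5=mapq5)
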