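"""Synthetic inputs for every pipeline stage.

Real fermented-tofu (Mao-tofu) measurements — amino-acid analyzer
tables, GC-MS peak tables, PacBio CCS amplicon reads — are emulated
here with the statistical structure the downstream analysis assumes, so
the whole pipeline is testable without laboratory data:

* 17-amino-acid profiles for three sample classes (BB: commercial
  product, MM: naturally fermented, CC: artificially inoculated) with
  log-normal noise of configurable CV around class means. Default class
  means are anchored to reported compositions of such products (e.g.
  Lys 7.35 g/100 g in CC, Pro 5.29 g/100 g in MM, class totals near
  54.7 / 78.1 / 76.3 g/100 g).
* GC-MS peak-area tables with a 2-octanol internal standard; compound
  areas are constructed as the exact inverse of the quantification
  formula, so planted concentrations are recoverable to machine
  precision.
* Full-length 16S reads (1400-1800 bp inserts) with 16-base barcodes on
  both ends (reverse-complemented at 3'), taxon-specific templates with
  point mutations, per-read predicted accuracy, and a configurable decoy
  fraction (out-of-length or low-accuracy reads) to exercise QC
  boundaries; a truth table maps every read to its sample and taxon.
* Taxa x sample and metabolite x sample matrices with planted monotone
  links via a Gaussian copula: the latent correlation equals the link
  strength, so Spearman |rho| increases monotonically with strength and
  reaches exactly 1 at strength 1.

All randomness flows from ``SynthConfig.seed`` through per-stage child
streams, so each generator is individually deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .amino_acids import AA_CODES, AminoAcidProfile
from .community import AmpliconRead, _revcomp
from .volatiles import IS_COMPOUND

__all__ = [
    "SynthConfig",
    "ConfigError",
    "DEFAULT_AA_MEANS",
    "DEFAULT_PROTEIN_PCT",
    "gen_amino_acid_profiles",
    "gen_volatile_table",
    "gen_barcodes",
    "gen_amplicon_reads",
    "gen_taxa_metabolite_dataset",
    "to_relative_pct",
    "write_reads",
    "profiles_to_tsv",
]


class ConfigError(ValueError):
    """Raised for invalid synthetic-data configuration."""


#: Default class mean contents (g / 100 g), anchored where reported
#: compositions of commercial (BB), naturally fermented (MM) and
#: inoculated (CC) product exist; remaining values are realistic
#: soy-hydrolysate levels chosen to match the class totals.
DEFAULT_AA_MEANS: dict[str, dict[str, float]] = {
    "BB": {
        "Asp": 6.2, "Glu": 13.17, "Ser": 2.6, "Gly": 2.2, "His": 1.4,
        "Arg": 3.6, "Thr": 2.1, "Ala": 2.3, "Pro": 2.37, "Tyr": 1.9,
        "Val": 2.6, "Met": 0.7, "Cys": 0.8, "Ile": 2.5, "Leu": 4.2,
        "Phe": 2.8, "Lys": 3.26,
    },
    "MM": {
        "Asp": 8.9, "Glu": 13.98, "Ser": 3.4, "Gly": 3.1, "His": 1.9,
        "Arg": 4.9, "Thr": 3.9, "Ala": 3.5, "Pro": 5.29, "Tyr": 2.6,
        "Val": 4.4, "Met": 1.1, "Cys": 1.0, "Ile": 4.3, "Leu": 6.6,
        "Phe": 3.9, "Lys": 5.3,
    },
    "CC": {
        "Asp": 8.2, "Glu": 11.21, "Ser": 2.9, "Gly": 2.7, "His": 2.0,
        "Arg": 4.2, "Thr": 4.3, "Ala": 3.2, "Pro": 3.9, "Tyr": 2.8,
        "Val": 5.1, "Met": 1.3, "Cys": 1.1, "Ile": 4.9, "Leu": 7.0,
        "Phe": 4.1, "Lys": 7.35,
    },
}

#: Default total protein (%) per class, as reported for such products.
DEFAULT_PROTEIN_PCT: dict[str, float] = {"BB": 18.40, "MM": 25.08, "CC": 22.07}

_VOLATILE_CLASSES = (
    "acid", "aldehyde", "alcohol", "ester", "phenol",
    "ketone", "sulfur", "heterocycle", "other",
)


@dataclass
class SynthConfig:
    """All knobs for the synthetic generators.

    ``planted_links`` entries are ``(taxon, metabolite, sign, strength)``
    with sign in {+1, -1} and strength in [0, 1]; taxa are named
    ``TaxonNN`` and metabolites ``MetabNN`` (1-based, zero-padded).
    """

    seed: int = 0
    # amino acids
    n_samples_per_class: int = 3
    class_names: tuple[str, ...] = ("BB", "MM", "CC")
    aa_class_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_AA_MEANS.items()}
    )
    protein_pct: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROTEIN_PCT)
    )
    aa_noise_cv: float = 0.05
    # volatiles
    n_volatiles: int = 20
    volatile_class_palette: tuple[str, ...] = _VOLATILE_CLASSES
    internal_standard_conc: float = 0.14 / 5.1
    # amplicon reads
    n_reads_per_sample: int = 200
    read_length_range: tuple[int, int] = (1400, 1800)
    accuracy_dist: tuple[float, float] = (0.97, 0.02)
    accuracy_floor: float = 0.90
    decoy_fraction: float = 0.0
    mutation_rate: float = 0.005
    n_taxa: int = 5
    # taxa / metabolite matrices
    n_corr_samples: int = 30
    n_metabolites: int = 8
    planted_links: list[tuple[str, str, int, float]] = field(default_factory=list)

    def validate(self) -> None:
        lo, hi = self.read_length_range
        if not (lo < hi):
            raise ConfigError("read_length_range min must be < max")
        if not (500 <= lo and hi <= 3000):
            raise ConfigError("read_length_range must lie within [500, 3000]")
        if self.internal_standard_conc <= 0:
            raise ConfigError("internal_standard_conc must be > 0")
        if self.n_volatiles < 1:
            raise ConfigError("n_volatiles must be >= 1")
        for cls, means in self.aa_class_means.items():
            unknown = set(means) - set(AA_CODES)
            if unknown:
                raise ConfigError(
                    f"unknown amino-acid codes for class {cls!r}: {sorted(unknown)}"
                )
        for taxon, metab, sign, strength in self.planted_links:
            if sign not in (1, -1):
                raise ConfigError(f"link sign must be +1/-1, got {sign}")
            if not (0.0 <= strength <= 1.0):
                raise ConfigError(f"link strength outside [0, 1]: {strength}")
        if not (0.0 <= self.decoy_fraction <= 1.0):
            raise ConfigError("decoy_fraction must be in [0, 1]")

    def _rng(self, stream: int) -> np.random.Generator:
        # distinct child stream per generator, all rooted at `seed`
        return np.random.default_rng([self.seed, stream])


def _lognormal_around(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Log-normal draw with expectation ``mean`` and coefficient of variation ``cv``."""
    if cv == 0:
        return mean
    sigma2 = np.log1p(cv ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(np.exp(rng.normal(mu, np.sqrt(sigma2))))


def gen_amino_acid_profiles(config: SynthConfig) -> list[AminoAcidProfile]:
    """One 17-amino-acid profile per sample, log-normal noise around class means."""
    config.validate()
    rng = config._rng(1)
    profiles = []
    for cls in config.class_names:
        means = config.aa_class_means[cls]
        pct = config.protein_pct.get(cls, 20.0)
        for i in range(config.n_samples_per_class):
            contents = {
                code: _lognormal_around(rng, means[code], config.aa_noise_cv)
                for code in means
            }
            profiles.append(AminoAcidProfile(f"{cls}{i + 1}", contents, pct))
    return profiles


def gen_volatile_table(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Peak-area table plus ground-truth concentrations.

    Compound areas are ``Ais * c / Cis`` for a planted concentration
    ``c``, i.e. the exact inverse of the quantification formula.
    """
    config.validate()
    rng = config._rng(2)
    palette = list(config.volatile_class_palette)
    cis = config.internal_standard_conc
    peak_rows, truth_rows = [], []
    compounds = [
        (f"compound_{j + 1:02d}", palette[j % len(palette)])
        for j in range(config.n_volatiles)
    ]
    for cls in config.class_names:
        for i in range(config.n_samples_per_class):
            sid = f"{cls}{i + 1}"
            ais = _lognormal_around(rng, 1.0e6, 0.2)
            for name, chem_class in compounds:
                conc = _lognormal_around(rng, 1.0, 0.8)
                peak_rows.append(
                    {"sample_id": sid, "compound": name, "chemical_class": chem_class,
                     "peak_area": ais * conc / cis}
                )
                truth_rows.append(
                    {"sample_id": sid, "compound": name, "true_conc_ug_per_g": conc}
                )
            peak_rows.append(
                {"sample_id": sid, "compound": IS_COMPOUND,
                 "chemical_class": "other", "peak_area": ais}
            )
    return pd.DataFrame(peak_rows), pd.DataFrame(truth_rows)


def gen_barcodes(rng: np.random.Generator, n: int) -> list[str]:
    """``n`` distinct random 16-base barcodes."""
    bases = np.array(list("ACGT"))
    out: list[str] = []
    seen = set()
    while len(out) < n:
        bc = "".join(rng.choice(bases, size=16))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    alphabet = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    for i in hits:
        choices = alphabet[alphabet != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def gen_amplicon_reads(
    config: SynthConfig,
) -> tuple[list[AmpliconRead], pd.DataFrame, dict[str, str]]:
    """Synthetic full-length 16S reads with barcodes, accuracy, truth labels.

    Returns ``(reads, truth, barcode_map)`` where ``truth`` has columns
    ``read_id, sample_id, taxon, genus, species, is_decoy`` and
    ``barcode_map`` maps 16-base barcodes to sample ids. Non-decoy reads
    always satisfy the default QC window (length within the configured
    range, accuracy at least ``accuracy_floor``); decoys violate exactly
    one criterion each.
    """
    config.validate()
    rng = config._rng(3)
    lo, hi = config.read_length_range
    n_samples = len(config.class_names) * config.n_samples_per_class
    sample_ids = [
        f"{cls}{i + 1}"
        for cls in config.class_names
        for i in range(config.n_samples_per_class)
    ]
    barcodes = gen_barcodes(rng, n_samples)
    barcode_map = dict(zip(barcodes, sample_ids))

    bases = np.array(list("ACGT"))
    taxa = []
    for t in range(config.n_taxa):
        length = int(rng.integers(lo, hi + 1))
        template = "".join(rng.choice(bases, size=length))
        taxa.append(
            {"taxon": f"Taxon{t + 1:02d}", "genus": f"Genus{t + 1:02d}",
             "species": f"Genus{t + 1:02d} sp{t + 1:02d}", "template": template}
        )

    mean_acc, sd_acc = config.accuracy_dist
    reads: list[AmpliconRead] = []
    truth_rows = []
    for bc, sid in barcode_map.items():
        weights = rng.dirichlet(np.full(config.n_taxa, 2.0))
        for r in range(config.n_reads_per_sample):
            rid = f"{sid}_r{r + 1:04d}"
            taxon = taxa[int(rng.choice(config.n_taxa, p=weights))]
            insert = _mutate(rng, taxon["template"], config.mutation_rate)
            accuracy = float(
                np.clip(rng.normal(mean_acc, sd_acc), config.accuracy_floor, 1.0)
            )
            is_decoy = bool(rng.random() < config.decoy_fraction)
            if is_decoy:
                kind = rng.integers(3)
                if kind == 0:  # too short
                    insert = insert[: max(1, lo - int(rng.integers(50, 200)))]
                elif kind == 1:  # too long
                    pad = "".join(rng.choice(bases, size=int(rng.integers(50, 200))))
                    insert = insert + pad * ((hi - len(insert)) // len(pad) + 2)
                    insert = insert[: hi + int(rng.integers(50, 200))]
                else:  # low accuracy
                    accuracy = float(rng.uniform(0.5, config.accuracy_floor - 1e-6))
            seq = bc + insert + _revcomp(bc)
            reads.append(AmpliconRead(rid, seq, accuracy))
            truth_rows.append(
                {"read_id": rid, "sample_id": sid, "taxon": taxon["taxon"],
                 "genus": taxon["genus"], "species": taxon["species"],
                 "is_decoy": is_decoy}
            )
    return reads, pd.DataFrame(truth_rows), barcode_map


def gen_taxa_metabolite_dataset(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Taxa and metabolite abundance matrices with planted monotone links.

    Latent Gaussian copula: for a planted link of strength ``s`` and
    sign ``g``, the metabolite's latent variable is
    ``g * (s * z_taxon + sqrt(1 - s^2) * eps)``; observed values are
    strictly monotone transforms, so Spearman rho is exactly ``g`` at
    s = 1 and |rho| grows monotonically with s. Unlinked pairs are
    independent. Matrices are feature x sample; taxa values are raw
    abundances (use :func:`to_relative_pct` to close to 100 %).
    """
    config.validate()
    rng = config._rng(4)
    n = config.n_corr_samples
    taxa_names = [f"Taxon{t + 1:02d}" for t in range(config.n_taxa)]
    metab_names = [f"Metab{m + 1:02d}" for m in range(config.n_metabolites)]

    linked_mets = {}
    for taxon, metab, sign, strength in config.planted_links:
        if taxon not in taxa_names:
            raise ConfigError(f"planted link references unknown taxon {taxon!r}")
        if metab not in metab_names:
            raise ConfigError(f"planted link references unknown metabolite {metab!r}")
        if metab in linked_mets:
            raise ConfigError(f"metabolite {metab!r} appears in multiple links")
        linked_mets[metab] = (taxon, sign, strength)

    z_taxa = {t: rng.normal(size=n) for t in taxa_names}
    taxa_scale = {t: float(rng.uniform(0.5, 2.0)) for t in taxa_names}
    taxa = pd.DataFrame(
        {t: taxa_scale[t] * np.exp(z_taxa[t]) for t in taxa_names}
    ).T
    taxa.columns = [f"S{i + 1:02d}" for i in range(n)]

    met_rows = {}
    for m in metab_names:
        if m in linked_mets:
            taxon, sign, strength = linked_mets[m]
            eps = rng.normal(size=n)
            latent = sign * (strength * z_taxa[taxon]
                             + np.sqrt(1.0 - strength ** 2) * eps)
        else:
            latent = rng.normal(size=n)
        met_rows[m] = np.exp(0.5 * latent)
    metabolites = pd.DataFrame(met_rows).T
    metabolites.columns = taxa.columns
    return taxa, metabolites


def to_relative_pct(matrix: pd.DataFrame) -> pd.DataFrame:
    """Close a feature x sample abundance matrix to per-sample percentages."""
    totals = matrix.sum(axis=0)
    return 100.0 * matrix / totals


def write_reads(reads: Sequence[AmpliconRead], fastq_path, sidecar_path) -> None:
    """Write reads as Phred-33 FASTQ plus a read_id/accuracy sidecar TSV.

    The FASTQ quality line uses one flat per-read quality derived from
    the predicted accuracy (capped at Q60); the sidecar carries the
    exact accuracy.
    """
    with open(fastq_path, "w") as fq, open(sidecar_path, "w") as sc:
        for read in reads:
            err = max(1.0 - read.accuracy, 1e-6)
            q = min(int(round(-10.0 * np.log10(err))), 60)
            fq.write(f"@{read.read_id}\n{read.sequence}\n+\n"
                     f"{chr(q + 33) * len(read.sequence)}\n")
            sc.write(f"{read.read_id}\t{read.accuracy:.6f}\n")


def profiles_to_tsv(profiles: Sequence[AminoAcidProfile], path) -> None:
    """Write profiles in long-form TSV (sample_id, aa_code, g_per_100g)."""
    rows = [
        {"sample_id": p.sample_id, "aa_code": code, "g_per_100g": value}
        for p in profiles
        for code, value in sorted(p.contents.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def truth_to_json(truth: pd.DataFrame, path) -> None:
    """Write a read -> taxon truth table as JSON."""
    with open(path, "w") as fh:
        json.dump(truth.to_dict(orient="records"), fh, indent=1)
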