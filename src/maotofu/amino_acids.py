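"""Amino-acid nutritional and taste scoring for fermented soy products.

Implements the classical amino-acid-balance evaluation chain used for
protein quality assessment of foods:

* **RAA** — ratio of each essential amino acid (EAA), expressed in mg per
  g protein, to the WHO/FAO reference pattern value.
* **RC** — RAA divided by the mean RAA; RC < 1 marks a relative
  deficiency and the minimum RC identifies the first limiting amino acid.
* **SRC** — ratio-coefficient score, ``100 - 100 * CV(RC)``; 100 means a
  perfectly balanced EAA profile.
* **Fuzzy closeness** — a [0, 1] similarity of a profile to a model
  protein (whole egg) via a normalized absolute-difference (Lang
  distance) sum scaled by a constant ``c`` (default 0.09).
* **TAV** — taste activity value, free amino-acid content divided by its
  taste threshold; TAV > 1 means the acid contributes to perceived taste.

Profiles hold the 17 amino acids measurable after acid hydrolysis
(tryptophan is destroyed by HCl hydrolysis and excluded by default).
Contents are stored as g per 100 g sample and converted to mg per g
protein via the sample's total protein percentage when scored against a
reference pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "AA_CODES",
    "EAA_CODES",
    "NEAA_CODES",
    "COMBINED_TERMS",
    "AminoAcidProfile",
    "ReferencePattern",
    "AminoAcidEvaluation",
    "TAVRecord",
    "ScoringError",
    "load_reference_pattern",
    "load_taste_thresholds",
    "to_mg_per_g_protein",
    "combined_terms",
    "compute_raa",
    "compute_rc_src",
    "compute_ratios",
    "fuzzy_closeness",
    "compute_tav",
    "evaluate_profile",
    "baseline_from_increase",
    "read_profiles_tsv",
]

#: The 17 amino acids quantifiable from an acid hydrolysate (no Trp).
AA_CODES: tuple[str, ...] = (
    "Ala", "Arg", "Asp", "Cys", "Glu", "Gly", "His", "Ile", "Leu",
    "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Tyr", "Val",
)

#: Essential amino acids among the 17 (His included; Trp not measurable).
EAA_CODES: frozenset[str] = frozenset(
    {"His", "Ile", "Leu", "Lys", "Met", "Phe", "Thr", "Val"}
)

NEAA_CODES: frozenset[str] = frozenset(AA_CODES) - EAA_CODES

#: Combined entries used by reference patterns (sulfur and aromatic pairs).
COMBINED_TERMS: dict[str, tuple[str, ...]] = {
    "Met+Cys": ("Met", "Cys"),
    "Phe+Tyr": ("Phe", "Tyr"),
}


class ScoringError(ValueError):
    """Raised when a profile cannot be scored (missing codes, bad basis)."""


@dataclass(frozen=True)
class AminoAcidProfile:
    """Per-sample amino-acid contents in g per 100 g sample.

    ``protein_pct`` is the total protein content of the sample (percent
    by mass); it is the conversion basis from g/100 g sample to mg/g
    protein when scoring against a reference pattern.
    """

    sample_id: str
    contents: Mapping[str, float]
    protein_pct: float = 100.0

    def __post_init__(self) -> None:
        for code, value in self.contents.items():
            if value < 0:
                raise ValueError(f"negative content for {code!r}: {value}")
        if not (0 < self.protein_pct <= 100):
            raise ValueError(
                f"protein_pct must be in (0, 100], got {self.protein_pct}"
            )


@dataclass(frozen=True)
class ReferencePattern:
    """A reference EAA pattern in mg per g protein (may use combined codes)."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        for code, value in self.values.items():
            if value <= 0:
                raise ValueError(f"non-positive reference value for {code!r}")


@dataclass
class TAVRecord:
    code: str
    content_mg_per_100g: float
    threshold_mg_per_100g: float
    tav: float
    contributes: bool
    taste_class: str


@dataclass
class AminoAcidEvaluation:
    """Full evaluation of one profile against a reference pattern."""

    sample_id: str
    raa: dict[str, float]
    rc: dict[str, float]
    src: float
    limiting_aa: str
    eaa_taa_pct: float
    eaa_neaa_pct: float
    taa_g_per_100g: float
    closeness_mu: float | None = None
    tav_records: list[TAVRecord] = field(default_factory=list)


def _load_pattern_tsv(filename: str, name: str) -> ReferencePattern:
    with resources.files("maotofu.data").joinpath(filename).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return ReferencePattern(name=name, values=dict(zip(df["code"], df["mg_per_g_protein"])))


def load_reference_pattern(name: str = "who_fao_1973") -> ReferencePattern:
    """Load a bundled reference pattern (``who_fao_1973`` or ``egg``)."""
    files = {"who_fao_1973": "who_fao_1973.tsv", "egg": "egg_reference.tsv"}
    try:
        return _load_pattern_tsv(files[name], name)
    except KeyError:
        raise ValueError(f"unknown reference pattern {name!r}") from None


def load_taste_thresholds() -> pd.DataFrame:
    """Bundled taste thresholds (mg per 100 g) with taste classes.

    Cys and Tyr have no established taste threshold in the compiled
    literature table and are absent; scoring them raises
    :class:`ScoringError`.
    """
    with resources.files("maotofu.data").joinpath("taste_thresholds.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def to_mg_per_g_protein(profile: AminoAcidProfile) -> dict[str, float]:
    """Convert g per 100 g sample to mg per g protein.

    g/100 g sample == 10 mg/g sample; dividing by the protein fraction
    (protein_pct / 100) yields mg per g protein.
    """
    factor = 1000.0 / profile.protein_pct
    return {code: v * factor for code, v in profile.contents.items()}


def combined_terms(
    contents: Mapping[str, float], codes: Iterable[str]
) -> dict[str, float]:
    """Resolve (possibly combined) reference codes against a content map.

    Combined codes like ``Met+Cys`` are summed from their components.
    Raises :class:`ScoringError` naming the first missing code.
    """
    out: dict[str, float] = {}
    for code in codes:
        if code in contents:
            out[code] = contents[code]
            continue
        parts = COMBINED_TERMS.get(code, (code,))
        try:
            out[code] = sum(contents[p] for p in parts)
        except KeyError as exc:
            raise ScoringError(f"profile is missing amino acid {exc.args[0]!r}") from None
    return out


def compute_raa(
    profile: AminoAcidProfile, ref: ReferencePattern
) -> dict[str, float]:
    """Amino-acid ratio: sample EAA content (mg/g protein) / pattern value."""
    mgg = to_mg_per_g_protein(profile)
    sample = combined_terms(mgg, ref.values.keys())
    return {code: sample[code] / ref.values[code] for code in ref.values}


def compute_rc_src(
    raa: Mapping[str, float], *, sample_sd: bool = False
) -> tuple[dict[str, float], float, str]:
    """Ratio coefficients, SRC score and the first limiting amino acid.

    RC_k = RAA_k / mean(RAA); SRC = 100 - 100 * CV where CV is the
    coefficient of variation of the RC values (population standard
    deviation by default, so SRC == 100 exactly for a uniform profile at
    any n; ``sample_sd=True`` switches to the n-1 divisor). The limiting
    amino acid is the argmin of RC, ties broken alphabetically.
    """
    if not raa:
        raise ScoringError("empty RAA map")
    if any(v <= 0 for v in raa.values()):
        raise ScoringError("RAA values must be positive")
    mean_raa = sum(raa.values()) / len(raa)
    rc = {code: v / mean_raa for code, v in raa.items()}
    mean_rc = sum(rc.values()) / len(rc)  # identically 1
    n = len(rc)
    ddof = 1 if sample_sd else 0
    if n - ddof <= 0:
        sd = 0.0
    else:
        sd = math.sqrt(sum((v - mean_rc) ** 2 for v in rc.values()) / (n - ddof))
    cv = sd / mean_rc
    src = 100.0 - cv * 100.0
    limiting = min(sorted(rc), key=rc.__getitem__)
    return rc, src, limiting


def compute_ratios(
    profile: AminoAcidProfile, eaa_set: frozenset[str] | set[str] = EAA_CODES
) -> tuple[float, float, float]:
    """EAA/TAA %, EAA/NEAA % and the total amino-acid content (TAA).

    Returns ``(eaa_taa_pct, eaa_neaa_pct, taa)``. If the profile holds
    no non-essential amino acids the EAA/NEAA ratio is undefined and a
    :class:`ScoringError` is raised.
    """
    unknown = set(eaa_set) - set(profile.contents)
    if unknown:
        raise ScoringError(f"EAA codes absent from profile: {sorted(unknown)}")
    eaa = sum(v for c, v in profile.contents.items() if c in eaa_set)
    taa = sum(profile.contents.values())
    neaa = taa - eaa
    if taa == 0:
        raise ScoringError("profile has zero total amino-acid content")
    if neaa == 0:
        raise ScoringError("EAA/NEAA undefined: no non-essential amino acids")
    return 100.0 * eaa / taa, 100.0 * eaa / neaa, taa


def fuzzy_closeness(
    profile: AminoAcidProfile | Mapping[str, float],
    egg: ReferencePattern | None = None,
    c: float = 0.09,
) -> float:
    """Closeness of a profile to the model (egg) protein via Lang distance.

    ``mu = 1 - c * sum_k |alpha_k - u_k| / (alpha_k + u_k)`` over the 7
    non-Trp EAA terms (sulfur and aromatic pairs combined). Each term
    lies in [0, 1], so ``mu`` lies in [1 - 7c, 1] — [0.37, 1] at the
    default c = 0.09 — and equals 1 iff the profile matches the model on
    every term.

    ``profile`` may be an :class:`AminoAcidProfile` (converted to mg/g
    protein) or a pre-converted mg/g-protein mapping keyed like the
    reference (combined codes allowed).
    """
    if egg is None:
        egg = load_reference_pattern("egg")
    if isinstance(profile, AminoAcidProfile):
        u = combined_terms(to_mg_per_g_protein(profile), egg.values.keys())
    else:
        u = combined_terms(profile, egg.values.keys())
    total = 0.0
    for code, alpha in egg.values.items():
        uk = u[code]
        denom = alpha + uk
        if denom == 0:
            raise ScoringError(f"degenerate closeness term for {code!r}: both zero")
        total += abs(alpha - uk) / denom
    return 1.0 - c * total


def compute_tav(
    free_aa_mg_per_100g: Mapping[str, float],
    thresholds: pd.DataFrame | None = None,
    *,
    invert: bool = False,
) -> tuple[list[TAVRecord], dict[str, list[str]]]:
    """Taste activity values and a per-taste-class contribution summary.

    TAV = content / threshold (both mg per 100 g); an amino acid
    contributes to taste iff TAV > 1 (strict). ``invert=True`` computes
    threshold / content instead, for comparison with sources using the
    reciprocal convention.

    Returns the records plus a map taste_class -> contributing codes.
    """
    if thresholds is None:
        thresholds = load_taste_thresholds()
    table = thresholds.set_index("code")
    records: list[TAVRecord] = []
    summary: dict[str, list[str]] = {}
    for code in sorted(free_aa_mg_per_100g):
        content = free_aa_mg_per_100g[code]
        if code not in table.index:
            raise ScoringError(f"no taste threshold for amino acid {code!r}")
        thr = float(table.at[code, "threshold_mg_per_100g"])
        taste = str(table.at[code, "taste_class"])
        if invert:
            tav = thr / content if content > 0 else math.inf
        else:
            tav = content / thr
        contributes = (tav < 1.0) if invert else (tav > 1.0)
        records.append(TAVRecord(code, content, thr, tav, contributes, taste))
        if contributes:
            summary.setdefault(taste, []).append(code)
    return records, summary


def evaluate_profile(
    profile: AminoAcidProfile,
    ref: ReferencePattern | None = None,
    egg: ReferencePattern | None = None,
    *,
    with_tav: bool = False,
) -> AminoAcidEvaluation:
    """Run the full nutritional evaluation of one profile."""
    if ref is None:
        ref = load_reference_pattern("who_fao_1973")
    raa = compute_raa(profile, ref)
    rc, src, limiting = compute_rc_src(raa)
    eaa_taa, eaa_neaa, taa = compute_ratios(profile)
    mu = fuzzy_closeness(profile, egg)
    ev = AminoAcidEvaluation(
        sample_id=profile.sample_id,
        raa=raa,
        rc=rc,
        src=src,
        limiting_aa=limiting,
        eaa_taa_pct=eaa_taa,
        eaa_neaa_pct=eaa_neaa,
        taa_g_per_100g=taa,
        closeness_mu=mu,
    )
    if with_tav:
        free_mg = {c: v * 1000.0 for c, v in profile.contents.items()}
        thr = load_taste_thresholds()
        scorable = {c: v for c, v in free_mg.items() if c in set(thr["code"])}
        ev.tav_records, _ = compute_tav(scorable, thr)
    return ev


def baseline_from_increase(value: float, pct_increase: float) -> float:
    """Back out a baseline from a value and its percent increase over it.

    E.g. a total of 78.07 reported as a 42.69 % increase over the
    baseline implies a baseline of ``78.07 / 1.4269``.
    """
    return value / (1.0 + pct_increase / 100.0)


def read_profiles_tsv(path, protein_pct: Mapping[str, float] | float = 100.0):
    """Read amino-acid profiles from TSV (long or wide form).

    Long form: columns ``sample_id, aa_code, g_per_100g``. Wide form:
    ``sample_id`` plus one column per amino-acid code. ``protein_pct``
    may be a scalar applied to all samples or a per-sample map.
    """
    df = pd.read_csv(path, sep="\t")
    profiles: list[AminoAcidProfile] = []

    def pct_for(sid: str) -> float:
        if isinstance(protein_pct, Mapping):
            return float(protein_pct[sid])
        return float(protein_pct)

    if {"sample_id", "aa_code", "g_per_100g"} <= set(df.columns):
        for sid, grp in df.groupby("sample_id", sort=False):
            contents = dict(zip(grp["aa_code"], grp["g_per_100g"]))
            profiles.append(AminoAcidProfile(str(sid), contents, pct_for(str(sid))))
    else:
        aa_cols = [c for c in df.columns if c != "sample_id"]
        for _, row in df.iterrows():
            sid = str(row["sample_id"])
            contents = {c: float(row[c]) for c in aa_cols}
            profiles.append(AminoAcidProfile(sid, contents, pct_for(sid)))
    return profiles
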