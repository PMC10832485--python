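"""Internal-standard semi-quantification of GC-MS volatile compounds.

Peak tables carry one 2-octanol internal-standard (IS) row per sample at
a known spiked concentration ``Cis``. Analyte concentrations follow the
single-point response-factor model

    C = (Ac / Ais) * Cis

where ``Ac`` and ``Ais`` are analyte and IS peak areas. Downstream
reports aggregate by chemical class (acid, aldehyde, alcohol, ester,
phenol, ketone, sulfur, heterocycle, other), filter to compounds whose
relative share of the per-sample total exceeds a threshold (1 % by
default, strict), and compare compound presence/absence across samples.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "CLASS_VOCAB",
    "IS_COMPOUND",
    "DEFAULT_CIS_UG_PER_ML",
    "QuantError",
    "quantify",
    "aggregate_classes",
    "filter_relative",
    "compare_samples",
    "normalize_compound",
]

CLASS_VOCAB: frozenset[str] = frozenset(
    {"acid", "aldehyde", "alcohol", "ester", "phenol",
     "ketone", "sulfur", "heterocycle", "other"}
)

IS_COMPOUND = "2-octanol"

# Naive in-matrix IS concentration for a 100 uL spike of 1.4 mg/L standard
# into ~5 mL of extract: 0.14 ug / 5.1 mL. Documented assumption; always
# overridable.
DEFAULT_CIS_UG_PER_ML = 0.14 / 5.1


class QuantError(ValueError):
    """Raised for malformed peak tables (missing/duplicate IS, bad areas)."""


def normalize_compound(name: str) -> str:
    """Case-fold and collapse whitespace for compound identity matching."""
    return " ".join(str(name).split()).casefold()


def quantify(peaks: pd.DataFrame, cis: float = DEFAULT_CIS_UG_PER_ML) -> pd.DataFrame:
    """Convert peak areas to concentrations against the internal standard.

    ``peaks`` needs columns ``sample_id, compound, chemical_class,
    peak_area`` with exactly one IS row (compound == "2-octanol", any
    case) per sample. Returns ``sample_id, compound, chemical_class,
    conc_ug_per_g, rel_pct`` with the IS row removed; ``rel_pct`` sums
    to 100 within each sample.
    """
    if cis <= 0:
        raise QuantError(f"internal-standard concentration must be > 0, got {cis}")
    required = {"sample_id", "compound", "chemical_class", "peak_area"}
    missing = required - set(peaks.columns)
    if missing:
        raise QuantError(f"peak table missing columns: {sorted(missing)}")

    peaks = peaks.copy()
    is_mask = peaks["compound"].map(normalize_compound) == IS_COMPOUND
    out_rows = []
    for sid, grp in peaks.groupby("sample_id", sort=False):
        is_rows = grp[is_mask.loc[grp.index]]
        if len(is_rows) == 0:
            raise QuantError(f"sample {sid!r} has no internal-standard row")
        if len(is_rows) > 1:
            raise QuantError(f"sample {sid!r} has {len(is_rows)} internal-standard rows")
        ais = float(is_rows["peak_area"].iloc[0])
        if ais <= 0:
            raise QuantError(f"sample {sid!r}: internal-standard area must be > 0")
        comp = grp[~is_mask.loc[grp.index]].copy()
        comp["conc_ug_per_g"] = comp["peak_area"] / ais * cis
        total = comp["conc_ug_per_g"].sum()
        comp["rel_pct"] = 100.0 * comp["conc_ug_per_g"] / total if total > 0 else 0.0
        out_rows.append(comp)
    out = pd.concat(out_rows, ignore_index=True)
    return out[["sample_id", "compound", "chemical_class", "conc_ug_per_g", "rel_pct"]]


def aggregate_classes(quant: pd.DataFrame) -> pd.DataFrame:
    """Per-sample compound count and total concentration by chemical class.

    Returns a tidy frame ``sample_id, chemical_class, n_compounds,
    total_conc_ug_per_g``. Unknown class labels raise
    :class:`QuantError`.
    """
    unknown = set(quant["chemical_class"]) - CLASS_VOCAB
    if unknown:
        raise QuantError(f"unknown chemical classes: {sorted(unknown)}")
    agg = (
        quant.groupby(["sample_id", "chemical_class"], sort=False)
        .agg(n_compounds=("compound", "size"), total_conc_ug_per_g=("conc_ug_per_g", "sum"))
        .reset_index()
    )
    return agg


def filter_relative(quant: pd.DataFrame, min_pct: float = 1.0) -> pd.DataFrame:
    """Keep compounds whose relative share strictly exceeds ``min_pct``.

    Rows are ordered by descending ``rel_pct`` within sample. An empty
    result is allowed.
    """
    kept = quant[quant["rel_pct"] > min_pct]
    return (
        kept.sort_values(["sample_id", "rel_pct"], ascending=[True, False])
        .reset_index(drop=True)
    )


def compare_samples(quant: pd.DataFrame) -> dict:
    """Presence/absence comparison of compound sets across samples.

    Compound identity is exact name match after case-folding and
    whitespace normalization. Returns the boolean compound x sample
    matrix, pairwise shared counts and per-sample unique counts.
    """
    samples = list(dict.fromkeys(quant["sample_id"]))
    if len(samples) < 2:
        raise QuantError("compare_samples needs at least two samples")
    q = quant.copy()
    q["compound_key"] = q["compound"].map(normalize_compound)
    presence = (
        q.assign(present=True)
        .pivot_table(index="compound_key", columns="sample_id", values="present",
                     aggfunc="any", fill_value=False)
        .reindex(columns=samples)
        .fillna(False)
        .astype(bool)
    )
    sets = {s: set(presence.index[presence[s]]) for s in samples}
    shared = {
        (a, b): len(sets[a] & sets[b])
        for i, a in enumerate(samples) for b in samples[i + 1:]
    }
    unique = {
        s: len(sets[s] - set.union(set(), *(sets[t] for t in samples if t != s)))
        for s in samples
    }
    return {"presence": presence, "shared": shared, "unique": unique}
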