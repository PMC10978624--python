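"""Curation of enzyme kinetic tables and the entropy-based promiscuity index.

The central quantity is the promiscuity index of an enzyme with measured
catalytic efficiencies ``x_1 .. x_n`` (one per substrate):

    I = -(1 / log n) * sum_i p_i log p_i,   p_i = x_i / sum_j x_j

i.e. the Shannon entropy of the efficiency shares, normalised by its maximum
``log n``.  ``I = 1`` means all substrates are catalysed equally well (a
generalist), ``I = 0`` means a single substrate carries all activity (a
specialist).  The index is invariant to the logarithm base, to rescaling all
efficiencies by a common factor, and to permutation of the substrates.

Curation turns a raw kinetic table (one row per enzyme-substrate measurement,
turnover number in 1/s and Michaelis constant in mM) into per-enzyme
efficiency profiles: substrate synonyms are merged, common cofactors removed,
replicate measurements averaged, enzymes whose protein accession appears
under more than one species discarded as mislabelled, and only enzymes with
at least two surviving substrates retained.
"""

from __future__ import annotations

import json
import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Cofactors removed during curation.  The canonical five most common
#: cofactors plus the frequent spelling variant "NAP+" of "NADP+".
DEFAULT_COFACTORS: tuple[str, ...] = ("ATP", "NAD+", "NADPH", "NADH", "NADP+", "NAP+")

#: Columns of the kinetic-table TSV dialect.
TSV_COLUMNS = ["enzyme_key", "ec", "species", "accession", "substrate", "kcat_per_s", "km_mM"]


class CurationError(ValueError):
    """Raised when curation cannot produce any eligible enzyme."""


@dataclass(frozen=True)
class KineticRecord:
    """One enzyme-substrate measurement.

    Parameters
    ----------
    enzyme_key
        Opaque enzyme identifier (EC number + species, or protein accession).
    kcat
        Turnover number, 1/s.
    km
        Michaelis constant, mM.
    """

    enzyme_key: str
    species: str
    substrate: str
    kcat: float
    km: float
    accession: str | None = None
    ec: str | None = None


@dataclass
class EnzymeProfile:
    """Per-substrate catalytic efficiencies (mM^-1 s^-1) of one enzyme."""

    enzyme_key: str
    efficiencies: dict[str, float]

    def __post_init__(self) -> None:
        if len(self.efficiencies) < 2:
            raise ValueError(f"profile {self.enzyme_key!r} needs >= 2 substrates")
        vals = np.asarray(list(self.efficiencies.values()), dtype=float)
        if (vals < 0).any() or not (vals > 0).any():
            raise ValueError(
                f"profile {self.enzyme_key!r}: efficiencies must be >= 0 with at least one > 0"
            )

    @property
    def n(self) -> int:
        return len(self.efficiencies)

    @property
    def values(self) -> np.ndarray:
        return np.asarray(list(self.efficiencies.values()), dtype=float)

    @property
    def best_efficiency(self) -> float:
        return float(self.values.max())

    @property
    def promiscuity(self) -> float:
        return promiscuity_index(self.values)


@dataclass(frozen=True)
class PromiscuitySummary:
    enzyme_key: str
    index: float
    n: int
    best_efficiency: float


@dataclass(frozen=True)
class DatasetSummary:
    """Dataset-level statistics of a curated set of enzyme profiles."""

    n_enzymes: int
    n_efficiencies: int
    median_efficiency: float
    median_index: float
    median_best_efficiency: float
    mean_substrates: float
    pearson_index_vs_log10_best: float
    pearson_p: float
    kendall_n_vs_index: float
    kendall_p: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def catalytic_efficiency(kcat: float, km: float) -> float:
    """Catalytic efficiency kcat/Km in mM^-1 s^-1.

    Both arguments must be strictly positive (kcat in 1/s, Km in mM).
    """
    if not (kcat > 0 and km > 0):
        raise ValueError(f"kcat and km must be positive, got kcat={kcat}, km={km}")
    return kcat / km


def promiscuity_index(efficiencies: Sequence[float] | np.ndarray) -> float:
    """Normalised-entropy promiscuity index of a vector of efficiencies.

    Zero entries contribute nothing (0 log 0 == 0 convention).  Requires at
    least two entries, all non-negative, at least one positive.
    """
    x = np.asarray(efficiencies, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need at least two efficiencies")
    if (x < 0).any():
        raise ValueError("efficiencies must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("at least one efficiency must be positive")
    p = x[x > 0] / total
    entropy = float(-(p * np.log(p)).sum())
    return entropy / math.log(x.size) if entropy > 0 else 0.0


def curate_records(
    records: Iterable[KineticRecord],
    synonym_map: Mapping[str, str] | None = None,
    cofactors: Sequence[str] = DEFAULT_COFACTORS,
    mean_of_ratios: bool = False,
) -> list[EnzymeProfile]:
    """Curate raw kinetic records into per-enzyme efficiency profiles.

    Steps, in order: drop records with non-positive kcat or Km (warning, not
    fatal); canonicalise substrate names through ``synonym_map``; drop rows
    whose canonical substrate is a cofactor; discard every enzyme sharing a
    protein accession that appears under more than one species (treated as a
    labelling error); average replicate measurements of the same
    enzyme-substrate pair (arithmetic mean of kcat and of Km separately, then
    efficiency = mean kcat / mean Km; with ``mean_of_ratios=True`` the mean
    of the per-replicate kcat/Km ratios is used instead); keep only enzymes
    with at least two surviving substrates.  Output is sorted by enzyme key.

    Raises
    ------
    CurationError
        If no enzyme survives filtering.
    """
    synonym_map = dict(synonym_map or {})
    cofactor_set = set(cofactors)

    records = list(records)
    if not records:
        raise CurationError("no input records")

    kept: list[KineticRecord] = []
    for rec in records:
        if not (rec.kcat > 0 and rec.km > 0):
            logger.warning(
                "dropping record %s / %s: non-positive kcat=%s km=%s",
                rec.enzyme_key, rec.substrate, rec.kcat, rec.km,
            )
            continue
        kept.append(rec)

    # Accessions listed under more than one species indicate mislabelling.
    accession_species: dict[str, set[str]] = defaultdict(set)
    for rec in kept:
        if rec.accession:
            accession_species[rec.accession].add(rec.species)
    bad_accessions = {a for a, sp in accession_species.items() if len(sp) > 1}
    bad_enzymes = {r.enzyme_key for r in kept if r.accession in bad_accessions}
    if bad_enzymes:
        logger.warning(
            "discarding %d enzyme(s) whose accession appears in more than one species",
            len(bad_enzymes),
        )

    # enzyme -> substrate -> list of (kcat, km)
    grouped: dict[str, dict[str, list[tuple[float, float]]]] = defaultdict(lambda: defaultdict(list))
    for rec in kept:
        if rec.enzyme_key in bad_enzymes:
            continue
        substrate = synonym_map.get(rec.substrate, rec.substrate)
        if substrate in cofactor_set:
            continue
        grouped[rec.enzyme_key][substrate].append((rec.kcat, rec.km))

    profiles: list[EnzymeProfile] = []
    for enzyme_key in sorted(grouped):
        substrates = grouped[enzyme_key]
        if len(substrates) < 2:
            continue
        efficiencies: dict[str, float] = {}
        for substrate, pairs in substrates.items():
            kcats = np.array([p[0] for p in pairs])
            kms = np.array([p[1] for p in pairs])
            if mean_of_ratios:
                efficiencies[substrate] = float((kcats / kms).mean())
            else:
                efficiencies[substrate] = float(kcats.mean() / kms.mean())
        profiles.append(EnzymeProfile(enzyme_key, efficiencies))

    if not profiles:
        raise CurationError("no eligible enzymes after curation")
    return profiles


def summarize_profiles(profiles: Sequence[EnzymeProfile]) -> list[PromiscuitySummary]:
    return [
        PromiscuitySummary(p.enzyme_key, p.promiscuity, p.n, p.best_efficiency)
        for p in profiles
    ]


def dataset_summary(profiles: Sequence[EnzymeProfile]) -> DatasetSummary:
    """Dataset-level medians and correlations for a curated profile set.

    Pearson correlation is between the promiscuity index and
    log10(best efficiency); Kendall's tau (tau-b, tie-corrected — substrate
    counts are heavily tied) is between substrate count and index.  With
    fewer than three profiles the correlations are reported as NaN rather
    than raising.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    indices = np.array([p.promiscuity for p in profiles])
    best = np.array([p.best_efficiency for p in profiles])
    ns = np.array([p.n for p in profiles])
    all_eff = np.concatenate([p.values for p in profiles])

    r = r_p = tau = tau_p = math.nan
    if len(profiles) >= 3:
        if np.ptp(indices) == 0 or np.ptp(best) == 0:
            logger.warning("constant index or best efficiency: Pearson r undefined")
        else:
            r, r_p = stats.pearsonr(indices, np.log10(best))
        if np.ptp(indices) == 0 or np.ptp(ns) == 0:
            logger.warning("all-tied input: Kendall tau undefined")
        else:
            tau, tau_p = stats.kendalltau(ns, indices)  # tau-b by default

    return DatasetSummary(
        n_enzymes=len(profiles),
        n_efficiencies=int(all_eff.size),
        median_efficiency=float(np.median(all_eff)),
        median_index=float(np.median(indices)),
        median_best_efficiency=float(np.median(best)),
        mean_substrates=float(ns.mean()),
        pearson_index_vs_log10_best=float(r),
        pearson_p=float(r_p),
        kendall_n_vs_index=float(tau),
        kendall_p=float(tau_p),
    )


def paired_efficiency_correlation(profiles: Sequence[EnzymeProfile], seed: int) -> float:
    """Pearson r between log10 efficiencies of one random substrate pair per enzyme.

    For each enzyme two substrates are drawn uniformly without replacement
    (both are used when the enzyme has exactly two); within each pair the
    assignment to (first, second) is randomised.  Reproducible from ``seed``.
    """
    if any(p.n < 2 for p in profiles):
        raise ValueError("every profile needs at least two substrates")
    rng = np.random.default_rng(seed)
    firsts, seconds = [], []
    for profile in profiles:
        vals = profile.values
        i, j = rng.choice(profile.n, size=2, replace=False)
        firsts.append(vals[i])
        seconds.append(vals[j])
    a = np.log10(np.asarray(firsts))
    b = np.log10(np.asarray(seconds))
    r, _ = stats.pearsonr(a, b)
    return float(r)


# ---------------------------------------------------------------------------
# I/O: the shared TSV dialect and summary outputs

def read_kinetic_table(path: str | Path) -> list[KineticRecord]:
    """Read the kinetic-table TSV (UTF-8, header row, empty accession allowed)."""
    df = pd.read_csv(path, sep="\t", dtype={"accession": "string", "ec": "string"})
    missing = set(TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"kinetic table {path} is missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        accession = None if pd.isna(row.accession) else str(row.accession)
        ec = None if pd.isna(row.ec) else str(row.ec)
        records.append(
            KineticRecord(
                enzyme_key=str(row.enzyme_key),
                species=str(row.species),
                substrate=str(row.substrate),
                kcat=float(row.kcat_per_s),
                km=float(row.km_mM),
                accession=accession,
                ec=ec,
            )
        )
    return records


def write_kinetic_table(records: Sequence[KineticRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "enzyme_key": [r.enzyme_key for r in records],
            "ec": [r.ec or "" for r in records],
            "species": [r.species for r in records],
            "accession": [r.accession or "" for r in records],
            "substrate": [r.substrate for r in records],
            "kcat_per_s": [repr(r.kcat) for r in records],
            "km_mM": [repr(r.km) for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_synonym_table(path: str | Path) -> dict[str, str]:
    """Read an alias -> canonical substrate-name TSV with columns alias, canonical."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["alias"].astype(str), df["canonical"].astype(str)))


def read_cofactor_list(path: str | Path) -> list[str]:
    """Read a cofactor list, one substrate name per line."""
    text = Path(path).read_text(encoding="utf-8")
    return [line.strip() for line in text.splitlines() if line.strip()]


def write_profile_summary(profiles: Sequence[EnzymeProfile], path: str | Path) -> None:
    rows = summarize_profiles(profiles)
    df = pd.DataFrame(
        {
            "enzyme_key": [s.enzyme_key for s in rows],
            "n": [s.n for s in rows],
            "promiscuity_index": [s.index for s in rows],
            "best_efficiency": [s.best_efficiency for s in rows],
        }
    )
    df.to_csv(path, index=False)


def write_dataset_summary(summary: DatasetSummary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2) + "\n", encoding="utf-8")
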