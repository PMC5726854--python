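"""Protein net charge, isoelectric point and proteome-wide distributions.

The net charge of a protein at a given pH is the Henderson-Hasselbalch sum
over its titratable groups,

    Z(pH) = sum_basic n_b / (1 + 10**(pH - pKa_b))
          - sum_acidic n_a / (1 + 10**(pKa_a - pH)),

with basic groups the N-terminus, His, Lys and Arg and acidic groups the
C-terminus, Asp, Glu, Cys and Tyr.  Two evaluation modes are provided:

``ipc``
    all titratable groups with the protein-optimised pKa set of the
    Isoelectric Point Calculator (the default for proteome statistics);
``counting``
    only the strong groups Asp, Glu, Lys, Arg plus the termini, with a
    classic textbook pKa table — the "count the charged residues" estimate.

Z(pH) is strictly decreasing, so the isoelectric point (Z = 0) is unique
and found by bisection.  Proteome-level helpers bin per-protein charge and
pI values (1 charge unit / 0.25 pH bins), optionally weighting by copy
number and optionally restricted to proteins annotated as cytoplasmic
(GO:0005737 cytoplasm / GO:0005829 cytosol).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "PkaSet",
    "ProteinRecord",
    "ChargeResult",
    "ProteomeDistribution",
    "load_pka",
    "net_charge",
    "isoelectric_point",
    "proteome_distribution",
    "filter_cytoplasmic",
    "read_fasta",
    "attach_go",
    "attach_copy_numbers",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_AA = set("BZXUO")
CYTOPLASM_GO = frozenset({"GO:0005737", "GO:0005829"})

#: residues titrated in counting mode (termini are always included)
_COUNTING_GROUPS = set("DEKR")


@dataclass(frozen=True)
class PkaSet:
    """Named table of dissociation constants for titratable groups."""

    name: str
    acidic: dict[str, float]
    basic: dict[str, float]

    def __post_init__(self) -> None:
        for table in (self.acidic, self.basic):
            for group, pka in table.items():
                if not 0.0 < pka < 14.0:
                    raise ValueError(f"pKa of {group} outside (0, 14)")
        if "Cterm" not in self.acidic or "Nterm" not in self.basic:
            raise ValueError("both termini must be present in the pKa set")


def load_pka(name: str = "ipc") -> PkaSet:
    """Load a shipped pKa table: ``"ipc"`` or ``"classic"``."""
    fname = {"ipc": "pka_ipc.json", "classic": "pka_classic.json"}.get(name)
    if fname is None:
        raise ValueError(f"unknown pKa set {name!r}")
    raw = json.loads(
        resources.files("cytodiff.data").joinpath(fname).read_text()
    )
    return PkaSet(name=raw["name"], acidic=raw["acidic"], basic=raw["basic"])


@dataclass
class ProteinRecord:
    """One protein: identifier, sequence and optional annotations."""

    id: str
    sequence: str
    copy_number: float | None = None
    go_terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.sequence = _clean_sequence(self.sequence, self.id)
        if self.copy_number is not None and self.copy_number < 0:
            raise ValueError("copy_number must be non-negative")


@dataclass(frozen=True)
class ChargeResult:
    net_charge: float
    ph: float
    mode: str


def _clean_sequence(sequence: str, rec_id: str = "?") -> str:
    seq = "".join(sequence.split()).upper().rstrip("*")
    if not seq:
        raise ValueError(f"empty sequence for record {rec_id}")
    unknown = set(seq) - STANDARD_AA - AMBIGUOUS_AA
    if unknown:
        warnings.warn(
            f"record {rec_id}: residues {sorted(unknown)} are not amino-acid "
            "codes and are treated as non-titratable"
        )
    elif set(seq) & AMBIGUOUS_AA:
        warnings.warn(
            f"record {rec_id}: ambiguity codes present, treated as "
            "non-titratable"
        )
    return seq


def _group_counts(
    seq: str, mode: str, include_termini: bool
) -> tuple[dict[str, int], dict[str, int]]:
    acidic: dict[str, int] = {}
    basic: dict[str, int] = {}
    acidic_groups = set("DECY") if mode == "ipc" else _COUNTING_GROUPS & set("DE")
    basic_groups = set("HKR") if mode == "ipc" else _COUNTING_GROUPS & set("KR")
    for aa in acidic_groups:
        n = seq.count(aa)
        if n:
            acidic[aa] = n
    for aa in basic_groups:
        n = seq.count(aa)
        if n:
            basic[aa] = n
    if include_termini:
        acidic["Cterm"] = 1
        basic["Nterm"] = 1
    return acidic, basic


def net_charge(
    sequence: str,
    ph: float = 7.5,
    pka_set: PkaSet | str | None = None,
    mode: str = "ipc",
    include_termini: bool = True,
) -> ChargeResult:
    """Henderson-Hasselbalch net charge of a sequence at a given pH.

    ``mode="ipc"`` titrates all groups with the IPC_protein table;
    ``mode="counting"`` titrates only Asp/Glu/Lys/Arg (plus termini) with
    the classic table.  An explicit ``pka_set`` overrides the default table
    of the mode.  ``include_termini=False`` drops the terminal groups,
    which makes the charge additive under concatenation (internal
    consistency checks only).
    """
    if mode not in ("ipc", "counting"):
        raise ValueError("mode must be 'ipc' or 'counting'")
    if not 0.0 < ph < 14.0:
        raise ValueError("ph must lie in (0, 14)")
    if pka_set is None:
        pka_set = load_pka("ipc" if mode == "ipc" else "classic")
    elif isinstance(pka_set, str):
        pka_set = load_pka(pka_set)
    seq = _clean_sequence(sequence)
    acidic, basic = _group_counts(seq, mode, include_termini)

    z = 0.0
    for group, n in basic.items():
        z += n / (1.0 + 10.0 ** (ph - pka_set.basic[group]))
    for group, n in acidic.items():
        z -= n / (1.0 + 10.0 ** (pka_set.acidic[group] - ph))
    return ChargeResult(net_charge=z, ph=ph, mode=mode)


def isoelectric_point(
    sequence: str,
    pka_set: PkaSet | str | None = None,
    mode: str = "ipc",
    tol: float = 1e-4,
) -> float:
    """pH at which the net charge vanishes, found by bisection.

    Z(pH) is strictly decreasing, so the zero is unique when it exists on
    (0, 14); otherwise the nearer boundary is returned with a warning.
    """
    lo, hi = 1e-9, 14.0 - 1e-9

    def z(ph: float) -> float:
        return net_charge(sequence, ph, pka_set, mode).net_charge

    z_lo, z_hi = z(lo), z(hi)
    if z_lo <= 0:
        warnings.warn("net charge negative over the whole pH range")
        return lo
    if z_hi >= 0:
        warnings.warn("net charge positive over the whole pH range")
        return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        z_mid = z(mid)
        if abs(z_mid) < tol:
            return mid
        if z_mid > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def filter_cytoplasmic(
    records: list[ProteinRecord],
    go_terms: frozenset[str] = CYTOPLASM_GO,
) -> list[ProteinRecord]:
    """Keep records annotated with at least one of the query GO terms."""
    return [r for r in records if r.go_terms & go_terms]


@dataclass
class ProteomeDistribution:
    """Per-protein table plus binned charge and pI histograms."""

    table: pd.DataFrame            # columns: id, net_charge, pi, weight
    charge_bins: np.ndarray        # bin edges, width 1, centred on integers
    charge_counts: np.ndarray
    pi_bins: np.ndarray            # bin edges, width 0.25 pH
    pi_counts: np.ndarray

    def charge_mean(self) -> float:
        w = self.table["weight"].to_numpy()
        return float(np.average(self.table["net_charge"], weights=w))


def proteome_distribution(
    records: list[ProteinRecord],
    ph: float = 7.5,
    weighting: str = "none",
    pka_set: PkaSet | str | None = None,
    mode: str = "ipc",
) -> ProteomeDistribution:
    """Charge and pI histograms over a set of proteins.

    ``weighting="copy_number"`` multiplies each protein by its copy number
    (all records must then carry one); ``"none"`` counts genes.
    """
    if not records:
        raise ValueError("at least one record is required")
    if weighting not in ("none", "copy_number"):
        raise ValueError("weighting must be 'none' or 'copy_number'")
    if weighting == "copy_number":
        missing = [r.id for r in records if r.copy_number is None]
        if missing:
            raise ValueError(
                f"copy-number weighting requested but absent for {missing[:5]}"
            )
        weights = np.array([r.copy_number for r in records], dtype=float)
    else:
        weights = np.ones(len(records))

    charges = np.array(
        [net_charge(r.sequence, ph, pka_set, mode).net_charge for r in records]
    )
    pis = np.array(
        [isoelectric_point(r.sequence, pka_set, mode) for r in records]
    )

    lo = np.floor(charges.min()) - 0.5
    hi = np.ceil(charges.max()) + 0.5
    charge_bins = np.arange(lo, hi + 1.0, 1.0)
    charge_counts, _ = np.histogram(charges, bins=charge_bins, weights=weights)
    pi_bins = np.arange(0.0, 14.0 + 0.25, 0.25)
    pi_counts, _ = np.histogram(pis, bins=pi_bins, weights=weights)

    table = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "net_charge": charges,
            "pi": pis,
            "weight": weights,
        }
    )
    return ProteomeDistribution(
        table=table,
        charge_bins=charge_bins,
        charge_counts=charge_counts,
        pi_bins=pi_bins,
        pi_counts=pi_counts,
    )


# ---------------------------------------------------------------------------
# I/O: FASTA plus UniProt-style TSV sidecars

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    return [
        ProteinRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def attach_go(
    records: list[ProteinRecord], tsv_path: str | Path
) -> list[ProteinRecord]:
    """Attach GO terms from a TSV with columns (id, go) where ``go`` is a
    semicolon-separated list of GO identifiers (UniProt column export)."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str).fillna("")
    mapping = {
        row[0]: {t.strip() for t in row[1].split(";") if t.strip()}
        for row in df.itertuples(index=False)
    }
    for r in records:
        r.go_terms = mapping.get(r.id, set())
    return records


def attach_copy_numbers(
    records: list[ProteinRecord], tsv_path: str | Path
) -> list[ProteinRecord]:
    """Attach copy numbers from a TSV with columns (id, count)."""
    df = pd.read_csv(tsv_path, sep="\t")
    mapping = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))
    for r in records:
        r.copy_number = mapping.get(r.id)
    return records
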