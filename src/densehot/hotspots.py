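"""Hot-spot labels from alanine-scanning affinities, and evaluation metrics.

A residue is an experimental hot spot when mutating it to alanine raises the
binding free energy by at least 2.0 kcal/mol:

    ddG = dG_mut - dG_wt >= 2.0 kcal/mol,      dG = RT ln Kd

with R the ideal gas constant, T = 298.15 K and Kd the dissociation constant
in molar units, so RT = (8.314/4184) * (273.15 + 25.0) ~ 0.5925 kcal/mol and
ddG = RT ln(Kd_mut / Kd_wt).

Predictions (vertex subsets of a residue interaction network) are scored with
precision, recall, F1 and F2.  F2 weights recall twice as much as precision,
which matches how sparse the experimental ground truth is: a residue never
assayed is not known to be a non-hot-spot, so missed predictions are cheaper
than missed hot spots.
"""

from __future__ import annotations

import io
import logging
import math
import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .graph import GraphInputError
from .rin import ContactNetwork, ResidueKey

logger = logging.getLogger(__name__)

__all__ = [
    "RT_KCAL_PER_MOL",
    "HOTSPOT_DDG_KCAL",
    "MutationRecord",
    "HotspotLabel",
    "EvaluationMetrics",
    "delta_g",
    "ddg",
    "label_hotspots",
    "evaluate",
    "aggregate",
    "read_skempi",
]

#: RT in kcal/mol at 25 C: (R in kcal) * (absolute temperature).
RT_KCAL_PER_MOL = (8.314 / 4184.0) * (273.15 + 25.0)
#: Experimental hot-spot threshold, inclusive.
HOTSPOT_DDG_KCAL = 2.0

AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class MutationRecord:
    """One point-mutation affinity measurement (SKEMPI-style)."""

    structure_id: str
    chain_id: str
    wild_type_aa: str   # 1-letter
    residue_number: int
    insertion_code: str
    mutant_aa: str      # 1-letter
    affinity_wt: float  # Kd, molar
    affinity_mut: float  # Kd, molar

    @property
    def site(self) -> Tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def is_alanine_scan(self) -> bool:
        return self.mutant_aa == "A"


@dataclass(frozen=True)
class HotspotLabel:
    site: Tuple[str, int, str]  # (chain, number, icode)
    is_hotspot: bool
    max_ddg: float


@dataclass(frozen=True)
class EvaluationMetrics:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    f2: float

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "f2": self.f2,
        }


def delta_g(kd: float) -> float:
    """Binding free energy RT ln(Kd) in kcal/mol (Kd in molar, > 0)."""
    if not kd > 0:
        raise GraphInputError(f"Kd must be positive, got {kd!r}")
    return RT_KCAL_PER_MOL * math.log(kd)


def ddg(record: MutationRecord) -> float:
    """ddG = dG_mut - dG_wt = RT ln(Kd_mut / Kd_wt) in kcal/mol."""
    return delta_g(record.affinity_mut) - delta_g(record.affinity_wt)


def _site_key(residue: ResidueKey) -> Tuple[str, int, str]:
    return (residue.chain_id, residue.residue_number, residue.insertion_code)


def label_hotspots(
    records: Iterable[MutationRecord],
    network: Optional[ContactNetwork] = None,
    aggregate_rule: str = "max",
) -> List[HotspotLabel]:
    """Per-residue hot-spot labels from alanine-mutation records.

    Only alanine mutants qualify.  Replicate measurements on one residue are
    combined by ``aggregate_rule`` ('max', the default: any experiment at or
    above 2.0 kcal/mol marks a hot spot; or 'mean').  When a network is given,
    records whose wild-type amino acid contradicts the structure's residue
    name are skipped with a warning.  Residues without any qualifying record
    carry no label.
    """
    if aggregate_rule not in ("max", "mean"):
        raise GraphInputError(f"unknown aggregate rule {aggregate_rule!r}")
    names: Dict[Tuple[str, int, str], str] = {}
    if network is not None:
        names = {_site_key(v): v.residue_name for v in network.graph.vertices}
    per_site: Dict[Tuple[str, int, str], List[float]] = {}
    for rec in records:
        if not rec.is_alanine_scan:
            continue
        site = rec.site
        if site in names:
            expected = AA_1TO3.get(rec.wild_type_aa.upper())
            if expected is not None and expected != names[site]:
                logger.warning(
                    "wild-type mismatch at %s: record says %s, structure has %s; skipped",
                    site, expected, names[site],
                )
                continue
        per_site.setdefault(site, []).append(ddg(rec))
    labels = []
    for site in sorted(per_site):
        values = per_site[site]
        agg = max(values) if aggregate_rule == "max" else sum(values) / len(values)
        labels.append(HotspotLabel(site=site, is_hotspot=agg >= HOTSPOT_DDG_KCAL, max_ddg=agg))
    return labels


def _fbeta(precision: float, recall: float, beta: float) -> float:
    denom = beta * beta * precision + recall
    if denom == 0:
        return 0.0
    return (1 + beta * beta) * precision * recall / denom


def evaluate(
    predicted: Iterable,
    labels: Sequence[HotspotLabel],
    network: Optional[ContactNetwork] = None,
    include_missing_hotspots: bool = False,
) -> EvaluationMetrics:
    """Score a predicted residue set against hot-spot labels.

    ``predicted`` may contain :class:`ResidueKey` vertices or (chain, number,
    icode) tuples.  Predicted residues without a hot-spot label count as false
    positives (unassayed residues are treated as negatives).  Hot spots absent
    from the network vertex set are excluded from the false negatives by
    default — no network method can predict them — unless
    ``include_missing_hotspots`` is set.
    """
    pred_sites = set()
    for p in predicted:
        pred_sites.add(_site_key(p) if isinstance(p, ResidueKey) else tuple(p))
    hot = {lab.site for lab in labels if lab.is_hotspot}
    if network is not None and not include_missing_hotspots:
        in_net = {_site_key(v) for v in network.graph.vertices}
        dropped = hot - in_net
        if dropped:
            logger.info("%d labelled hot spots absent from the network; excluded from FN",
                        len(dropped))
        hot &= in_net
    tp = len(pred_sites & hot)
    fp = len(pred_sites - hot)
    fn = len(hot - pred_sites)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return EvaluationMetrics(
        tp=tp, fp=fp, fn=fn,
        precision=precision, recall=recall,
        f1=_fbeta(precision, recall, 1.0),
        f2=_fbeta(precision, recall, 2.0),
    )


def aggregate(per_complex: Sequence[EvaluationMetrics]) -> dict:
    """Unweighted mean of precision/recall/F1/F2 across complexes."""
    if not per_complex:
        raise GraphInputError("no per-complex metrics to aggregate")
    k = len(per_complex)
    return {
        "n_complexes": k,
        "precision": sum(m.precision for m in per_complex) / k,
        "recall": sum(m.recall for m in per_complex) / k,
        "f1": sum(m.f1 for m in per_complex) / k,
        "f2": sum(m.f2 for m in per_complex) / k,
    }


# ---------------------------------------------------------------------------
# SKEMPI-style tables
# ---------------------------------------------------------------------------

# e.g. TI38A: wt T, chain I, position 38, mutant A; an optional lowercase
# insertion-code letter may precede the mutant amino acid (YC100eF style).
_MUTATION_RE = re.compile(r"^([A-Z])([A-Za-z0-9])(\d+)([a-z]?)([A-Z])$")

DEFAULT_COLUMNS = {
    "pdb": "#Pdb",
    "mutation": "Mutation(s)_cleaned",
    "affinity_mut": "Affinity_mut_parsed",
    "affinity_wt": "Affinity_wt_parsed",
}


def read_skempi(
    source,
    delimiter: str = ";",
    columns: Optional[Dict[str, str]] = None,
) -> List[MutationRecord]:
    """Parse a SKEMPI-2.0-style mutation table into records.

    Mutation fields look like ``TI38A``: wild-type T, chain I, position 38
    (an optional insertion-code letter may follow), mutant A.  Only
    single-point mutations are used; multi-mutations (comma-separated) and
    rows with unparseable affinities are skipped.  The PDB field may carry
    chain annotations (``1BRS_A_D``); only the leading identifier is kept.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep=delimiter)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise GraphInputError(
            f"mutation table is missing columns {missing}; present: {list(df.columns)}"
        )
    records = []
    for _, row in df.iterrows():
        mut_field = str(row[cols["mutation"]]).strip()
        if "," in mut_field:
            continue
        m = _MUTATION_RE.match(mut_field)
        if not m:
            logger.warning("unparseable mutation %r; skipped", mut_field)
            continue
        wt, chain, pos, icode, mut = m.groups()
        icode = icode.upper()
        try:
            kd_wt = float(row[cols["affinity_wt"]])
            kd_mut = float(row[cols["affinity_mut"]])
        except (TypeError, ValueError):
            continue
        if not (kd_wt > 0 and kd_mut > 0):
            continue
        pdb = str(row[cols["pdb"]]).split("_")[0].strip()
        records.append(
            MutationRecord(
                structure_id=pdb,
                chain_id=chain,
                wild_type_aa=wt,
                residue_number=int(pos),
                insertion_code=icode,
                mutant_aa=mut,
                affinity_wt=kd_wt,
                affinity_mut=kd_mut,
            )
        )
    return records
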