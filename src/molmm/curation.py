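"""Hierarchical-confidence curation of multi-source bioactivity records.

The screening workflow turns a heterogeneous table of assay records into
three tiers of labeled compound sets:

* ``inh`` — refined inhibitor / non-inhibitor labels, from annotated
  in vitro inhibition assays (IC50/Ki) aggregated over hierarchical assay
  trees (compound -> probe substrate -> cell line) by majority voting,
  merged with in vivo digoxin AUC-ratio calls (which take precedence);
* ``sub`` — refined substrate / non-substrate labels from annotated
  efflux-ratio assays (deduplicated per cell line, no cross-level voting);
* ``noisy`` — a large low-confidence allocrite / non-allocrite set built
  from everything the refined screens excluded (unannotated records,
  conflicting leaves, ambiguous potency bands, voting exclusions).

Compounds are keyed by their cleaned canonical SMILES.  Overlaps between
tiers are removed from the lower-confidence tier, so the refined and noisy
sets are disjoint by construction.

Label thresholds: IC50 <= 15 uM strong, >= 50 uM non-inhibitor, the band
in between ambiguous ("moderate"); Ki is converted to the IC50 scale by
IC50 = 2*Ki (competitive-inhibition boundary condition); efflux ratio > 2
marks a substrate; in vivo digoxin AUC ratio >= 1.25 marks an inhibitor,
< 1.125 a non-inhibitor, with the gap excluded.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "AssayRecord", "TieredDatasets", "CurationConfig", "clean_structure",
    "label_inhibition", "label_efflux", "label_invivo", "build_inhibition_tree",
    "dedupe_leaves", "aggregate_inhibition", "assemble_tiers", "compare_datasets",
]

ASSAY_KINDS = {"invitro_inhibition", "invitro_efflux", "invivo_inhibition"}
_KIND_MEASURES = {
    "invitro_inhibition": {"IC50", "Ki"},
    "invitro_efflux": {"ER"},
    "invivo_inhibition": {"AUC_ratio"},
}

# elements accepted in an organic fragment; bare alkali/alkaline-earth ions
# are treated as pharmaceutical counterions and stripped
_ORGANIC_ELEMENTS = {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl",
                     "As", "Se", "Br", "Te", "I"}
_COUNTERION_ELEMENTS = {"Li", "Na", "K", "Rb", "Cs", "Mg", "Ca", "Sr", "Ba",
                        "Zn"}


@dataclass(frozen=True)
class AssayRecord:
    """One normalized experimental measurement with provenance metadata."""

    smiles: str
    assay_kind: str
    measure: str
    value: float
    probe_substrate: str | None = None
    cell_line: str | None = None
    annotated: bool = True

    def __post_init__(self):
        if self.assay_kind not in ASSAY_KINDS:
            raise ValueError(f"unknown assay_kind {self.assay_kind!r}")
        if self.measure not in _KIND_MEASURES[self.assay_kind]:
            raise ValueError(
                f"{self.assay_kind} requires measure in "
                f"{sorted(_KIND_MEASURES[self.assay_kind])}, got {self.measure!r}")
        if not (self.value > 0):
            raise ValueError("value must be positive")


@dataclass
class TieredDatasets:
    """Refined INH/SUB label maps plus the noisy allocrite map (disjoint)."""

    inh: dict[str, str] = field(default_factory=dict)
    sub: dict[str, str] = field(default_factory=dict)
    noisy: dict[str, str] = field(default_factory=dict)
    rejected: dict[str, str] = field(default_factory=dict)  # raw smiles -> reason

    def check_disjoint(self) -> None:
        refined = set(self.inh) | set(self.sub)
        overlap = refined & set(self.noisy)
        if overlap:
            raise AssertionError(f"tier overlap: {sorted(overlap)[:5]}")


@dataclass
class CurationConfig:
    """Column mapping and the metadata ('annotated') predicate.

    The exact metadata criteria are a config knob: by default a record
    counts as annotated when its ``annotated`` column is true, or — if the
    column is absent — when the metadata fields its assay kind requires
    (probe substrate and cell line for inhibition, cell line for efflux)
    are present.
    """

    columns: dict[str, str] = field(default_factory=dict)
    unit_scale: dict[str, float] = field(default_factory=lambda: {"uM": 1.0,
                                                                  "nM": 1e-3,
                                                                  "mM": 1e3})

    def column(self, name: str) -> str:
        return self.columns.get(name, name)


# ---------------------------------------------------------------------
# structure cleaning
# ---------------------------------------------------------------------

def clean_structure(raw_smiles: str) -> tuple[str | None, str | None]:
    """Canonicalize a structure: salt strip, neutralize, reject non-organics.

    Returns ``(canonical_smiles, None)`` on success or ``(None, reason)``
    with reason in {"unparseable", "inorganic", "metal_complex"}.
    """
    mol = Chem.MolFromSmiles(raw_smiles) if isinstance(raw_smiles, str) else None
    if mol is None:
        return None, "unparseable"
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = []
    for frag in frags:
        symbols = {a.GetSymbol() for a in frag.GetAtoms()}
        if symbols <= _ORGANIC_ELEMENTS and "C" in symbols:
            organic.append(frag)
        elif symbols <= _ORGANIC_ELEMENTS or (
                frag.GetNumAtoms() == 1 and symbols <= _COUNTERION_ELEMENTS):
            continue  # carbon-free salt/counterion fragment: stripped
        else:
            # fragment carrying a metal outside the simple-counterion set
            return None, "metal_complex"
    if not organic:
        return None, "inorganic"
    largest = max(organic, key=lambda m: m.GetNumHeavyAtoms())
    largest = rdMolStandardize.Uncharger().uncharge(largest)
    try:
        Chem.SanitizeMol(largest)
    except Exception:
        return None, "unparseable"
    return Chem.MolToSmiles(largest), None


# ---------------------------------------------------------------------
# label rules
# ---------------------------------------------------------------------

def label_inhibition(value: float, measure: str = "IC50") -> str:
    """Potency band from an in vitro inhibition measurement (uM scale).

    Ki is first mapped to the IC50 scale by IC50 = 2*Ki, then
    IC50 <= 15 -> "strong", >= 50 -> "non_inhibitor", else "moderate".
    """
    if not (value > 0):
        raise ValueError("inhibition value must be positive")
    if measure == "Ki":
        value = 2.0 * value
    elif measure != "IC50":
        raise ValueError(f"measure must be IC50 or Ki, got {measure!r}")
    if value <= 15.0:
        return "strong"
    if value >= 50.0:
        return "non_inhibitor"
    return "moderate"


def label_efflux(er: float) -> str:
    """ER > 2 -> substrate, otherwise non-substrate."""
    if not (er > 0):
        raise ValueError("efflux ratio must be positive")
    return "substrate" if er > 2.0 else "non_substrate"


def label_invivo(auc_ratio: float) -> str:
    """Digoxin AUC ratio: >= 1.25 inhibitor, < 1.125 non-inhibitor, gap excluded."""
    if not (auc_ratio > 0):
        raise ValueError("AUC ratio must be positive")
    if auc_ratio >= 1.25:
        return "inhibitor"
    if auc_ratio < 1.125:
        return "non_inhibitor"
    return "excluded"


# ---------------------------------------------------------------------
# assay trees and aggregation
# ---------------------------------------------------------------------

def build_inhibition_tree(records: list[AssayRecord]) -> dict:
    """Three-level tree: probe substrate -> cell line -> leaf label list."""
    tree: dict = defaultdict(lambda: defaultdict(list))
    for rec in records:
        tree[rec.probe_substrate][rec.cell_line].append(
            label_inhibition(rec.value, rec.measure))
    return {p: dict(cells) for p, cells in tree.items()}


def dedupe_leaves(tree: dict) -> dict:
    """Collapse duplicate labels per leaf; drop leaves with conflicts."""
    out: dict = {}
    for probe, cells in tree.items():
        kept = {}
        for cell, labels in cells.items():
            distinct = set(labels)
            if len(distinct) == 1:
                kept[cell] = [distinct.pop()]
        if kept:
            out[probe] = kept
    return out


def vote(labels: list[str]) -> str:
    """Majority-vote rule applied at one internal tree node.

    Only strong/moderate labels present: "inhibitor" iff strong strictly
    outnumber moderate, otherwise excluded.  Only non-inhibitor labels:
    "non_inhibitor".  Any mixture of the two sides: excluded.
    """
    counts = defaultdict(int)
    for lab in labels:
        counts[lab] += 1
    if not counts:
        raise ValueError("cannot vote over an empty label set")
    keys = set(counts)
    if keys <= {"strong", "moderate"}:
        return "inhibitor" if counts["strong"] > counts["moderate"] else "excluded"
    if keys == {"non_inhibitor"}:
        return "non_inhibitor"
    return "excluded"


_PROPAGATE = {"inhibitor": "strong", "non_inhibitor": "non_inhibitor"}


def aggregate_inhibition(tree: dict) -> str:
    """Bottom-up aggregation from cell-line nodes up to probe nodes.

    Excluded child nodes drop out of their parent's vote (their records
    feed the noisy tier); a compound whose surviving children all vote
    excluded is excluded.  Returns "inhibitor", "non_inhibitor" or
    "excluded".
    """
    if not tree:
        raise ValueError("empty assay tree")
    deduped = dedupe_leaves(tree)
    probe_labels = []
    for cells in deduped.values():
        cell_labels = [labs[0] for labs in cells.values()]
        verdict = vote(cell_labels)
        if verdict != "excluded":
            probe_labels.append(_PROPAGATE[verdict])
    if not probe_labels:
        return "excluded"
    return vote(probe_labels)


# ---------------------------------------------------------------------
# tier assembly
# ---------------------------------------------------------------------

def records_from_table(df: pd.DataFrame, config: CurationConfig | None = None,
                       ) -> tuple[list[AssayRecord], dict[str, str]]:
    """Parse, clean and normalize a raw record table.

    Applies structure cleaning (compound identity = cleaned canonical
    SMILES), unit normalization to uM, and the annotated predicate.
    Returns the record list and a map raw smiles -> rejection reason.
    """
    cfg = config or CurationConfig()
    col = cfg.column
    rejected: dict[str, str] = {}
    canon_cache: dict[str, str | None] = {}
    records: list[AssayRecord] = []
    has_annot = col("annotated") in df.columns
    has_units = col("units") in df.columns
    for row in df.itertuples(index=False):
        row = row._asdict()
        raw = row[col("smiles")]
        if raw not in canon_cache:
            canon, reason = clean_structure(raw)
            canon_cache[raw] = canon
            if canon is None:
                rejected[raw] = reason
        canon = canon_cache[raw]
        if canon is None:
            continue
        kind = row[col("assay_kind")]
        value = float(row[col("value")])
        if has_units and kind == "invitro_inhibition":
            value *= cfg.unit_scale[row[col("units")]]
        probe = row.get(col("probe_substrate"))
        cell = row.get(col("cell_line"))
        probe = None if pd.isna(probe) else probe
        cell = None if pd.isna(cell) else cell
        if has_annot:
            annotated = bool(row[col("annotated")])
        elif kind == "invitro_inhibition":
            annotated = probe is not None and cell is not None
        elif kind == "invitro_efflux":
            annotated = cell is not None
        else:
            annotated = True
        records.append(AssayRecord(canon, kind, row[col("measure")], value,
                                   probe, cell, annotated))
    return records, rejected


def _refined_inh_label(invitro: list[AssayRecord],
                       invivo: list[AssayRecord]) -> str:
    """INH call for one compound; in vivo evidence takes precedence."""
    if invivo:
        labels = {label_invivo(r.value) for r in invivo} - {"excluded"}
        if len(labels) == 1:
            return labels.pop()
        if len(labels) > 1:
            return "excluded"
        # all in the 1.125-1.25 gap: fall through to in vitro evidence
    if invitro:
        return aggregate_inhibition(build_inhibition_tree(invitro))
    return "excluded"


def _refined_sub_label(records: list[AssayRecord]) -> str:
    """SUB call: leaf-level dedupe per cell line only, no cross-level vote."""
    leaves = defaultdict(list)
    for rec in records:
        leaves[rec.cell_line].append(label_efflux(rec.value))
    surviving = set()
    for labs in leaves.values():
        distinct = set(labs)
        if len(distinct) == 1:
            surviving.add(distinct.pop())
    if len(surviving) == 1:
        return surviving.pop()
    return "excluded"


_ALLOCRITE_EVIDENCE = {"strong", "moderate", "substrate", "inhibitor", "excluded_gap"}
_NON_EVIDENCE = {"non_inhibitor", "non_substrate"}


def _record_evidence(rec: AssayRecord) -> str:
    if rec.assay_kind == "invitro_inhibition":
        lab = label_inhibition(rec.value, rec.measure)
    elif rec.assay_kind == "invitro_efflux":
        lab = label_efflux(rec.value)
    else:
        lab = label_invivo(rec.value)
        if lab == "excluded":
            lab = "excluded_gap"   # in the AUC gap: weak interaction evidence
    return lab


def assemble_tiers(records: list[AssayRecord],
                   rejected: dict[str, str] | None = None) -> TieredDatasets:
    """Assemble refined INH/SUB tiers and the noisy allocrite tier.

    Annotated records feed the refined screens; every record the refined
    screens did not turn into a refined label (unannotated, ambiguous,
    conflicting, excluded) contributes interaction evidence to the noisy
    tier.  Compounds that earned a refined label are removed from the
    noisy tier (higher confidence wins).
    """
    by_compound: dict[str, list[AssayRecord]] = defaultdict(list)
    for rec in records:
        by_compound[rec.smiles].append(rec)

    tiers = TieredDatasets(rejected=dict(rejected or {}))
    for smi, recs in by_compound.items():
        ann = [r for r in recs if r.annotated]
        invitro_inh = [r for r in ann if r.assay_kind == "invitro_inhibition"]
        invivo = [r for r in ann if r.assay_kind == "invivo_inhibition"]
        efflux = [r for r in ann if r.assay_kind == "invitro_efflux"]

        inh_label = (_refined_inh_label(invitro_inh, invivo)
                     if (invitro_inh or invivo) else "excluded")
        sub_label = _refined_sub_label(efflux) if efflux else "excluded"
        if inh_label != "excluded":
            tiers.inh[smi] = inh_label
        if sub_label != "excluded":
            tiers.sub[smi] = sub_label

        if inh_label == "excluded" and sub_label == "excluded":
            evidence = {_record_evidence(r) for r in recs}
            if evidence & _ALLOCRITE_EVIDENCE:
                tiers.noisy[smi] = "allocrite"
            elif evidence & _NON_EVIDENCE:
                tiers.noisy[smi] = "non_allocrite"

    # overlap removal: higher-confidence tiers win
    for smi in set(tiers.inh) | set(tiers.sub):
        tiers.noisy.pop(smi, None)
    tiers.check_disjoint()
    return tiers


def curate(df: pd.DataFrame, config: CurationConfig | None = None) -> TieredDatasets:
    """Full workflow: parse + clean + label + aggregate + tier assembly."""
    records, rejected = records_from_table(df, config)
    return assemble_tiers(records, rejected)


# ---------------------------------------------------------------------
# cross-dataset comparison
# ---------------------------------------------------------------------

@dataclass
class DatasetComparison:
    confusion: pd.DataFrame           # rows: labels in a, cols: labels in b
    accuracy: float                   # percent agreement on the overlap
    precision: dict[str, float]       # per label of a, percent
    n_overlap: int


def compare_datasets(a: dict[str, str], b: dict[str, str]) -> DatasetComparison:
    """Confusion matrix, accuracy and per-class precision on the overlap.

    ``a`` plays the role of the lower-confidence predictions, ``b`` the
    higher-confidence reference; only shared compounds are compared.
    """
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValueError("datasets share no compounds")
    labels_a = sorted({a[s] for s in shared})
    labels_b = sorted({b[s] for s in shared})
    mat = pd.DataFrame(0, index=labels_a, columns=labels_b)
    for s in shared:
        mat.loc[a[s], b[s]] += 1
    agree = sum(1 for s in shared if a[s] == b[s])
    precision = {}
    for lab in labels_a:
        called = sum(1 for s in shared if a[s] == lab)
        correct = sum(1 for s in shared if a[s] == lab and b[s] == lab)
        precision[lab] = 100.0 * correct / called if called else float("nan")
    return DatasetComparison(mat, 100.0 * agree / len(shared), precision,
                             len(shared))
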