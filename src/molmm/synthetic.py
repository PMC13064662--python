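"""Synthetic fixtures: multi-source assay-record tables and planted-signal
descriptor sets.

Nothing here attempts realistic ABCB1 pharmacology.  The generators only
reproduce the *statistical* structure the pipeline must cope with:

* assay records from several assay kinds (in vitro inhibition with IC50 or
  Ki, in vitro efflux with efflux ratios, in vivo inhibition with AUC
  ratios), with duplicates, within-leaf conflicts and records stripped of
  probe/cell-line metadata (which the curation stage must route to the
  noisy tier);
* descriptor matrices drawn as correlated Gaussian blocks carrying a
  class-conditional mean shift on a subset of dimensions, with an
  independently label-flipped "noisy" copy of the labels — the scarce
  clean / abundant corrupted setting the two-stage trainer is built for.

Every generator is deterministic given ``FixtureSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FixtureSpec", "generate_assay_records", "generate_signal_molecules",
           "enumerate_smiles"]


@dataclass
class FixtureSpec:
    """Parameters of a synthetic study; all proportions live in [0, 1]."""

    n_compounds: int = 100
    n_records_per_compound: tuple[int, int] = (1, 4)   # inclusive range
    frac_missing_metadata: float = 0.0
    conflict_rate: float = 0.0
    noisy_flip_rate: float = 0.0
    n_descriptors: int = 256
    signal_dims: int = 10
    effect_size: float = 1.0
    block_size: int = 8
    block_rho: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        if self.n_compounds <= 0:
            raise ValueError("n_compounds must be positive")
        lo, hi = self.n_records_per_compound
        if lo < 1 or hi < lo:
            raise ValueError("n_records_per_compound must be a nonempty 1-based range")
        for name in ("frac_missing_metadata", "conflict_rate", "noisy_flip_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if self.signal_dims > self.n_descriptors:
            raise ValueError("signal_dims cannot exceed n_descriptors")
        if self.signal_dims < 0 or self.n_descriptors <= 0:
            raise ValueError("descriptor counts must be positive")
        if self.block_size <= 0:
            raise ValueError("block_size must be positive")


# ---------------------------------------------------------------------
# SMILES enumeration
# ---------------------------------------------------------------------

_CHAIN_CAPS = ["", "O", "N", "C(=O)O", "C(C)C", "c1ccccc1", "C(=O)N", "OC"]


def enumerate_smiles(n: int, with_salts: bool = False,
                     with_metal_decoy: bool = False) -> list[str]:
    """Deterministic list of ``n`` distinct small-organic SMILES.

    Simple alkane/alcohol/amine/acid chains; optionally the acids appear
    as sodium carboxylate salts, and one iron-complex decoy can be
    appended so structure cleaning has material to reject.
    """
    from rdkit import Chem

    out: list[str] = []
    seen = set()
    length = 1
    while len(out) < n:
        for cap in _CHAIN_CAPS:
            smi = Chem.CanonSmiles("C" * length + cap)
            if smi not in seen:
                seen.add(smi)
                out.append(smi)
            if len(out) >= n:
                break
        length += 1
    if with_salts:
        out = [s.replace("C(=O)O", "C(=O)[O-].[Na+]") if i % 5 == 0 else s
               for i, s in enumerate(out)]
    if with_metal_decoy and out:
        out[-1] = "[Fe+2].[O-]C(=O)CC([O-])=O"
    return out[:n]


# ---------------------------------------------------------------------
# assay-record tables
# ---------------------------------------------------------------------

_PROBES = ["digoxin", "rhodamine123", "calcein-AM"]
_CELLS = ["MDCK-MDR1", "Caco-2", "LLC-PK1"]


def _inhibition_value(rng, inhibitor: bool, conflicting: bool) -> tuple[str, float]:
    """Draw an (measure, value) pair in the band matching the target label."""
    want_inhibitor = inhibitor != conflicting
    measure = "IC50" if rng.random() < 0.7 else "Ki"
    if want_inhibitor:
        ic50 = rng.uniform(0.5, 15.0)          # strong band, inclusive at 15
    else:
        ic50 = rng.uniform(50.0, 200.0)        # non-inhibitor band
    value = ic50 / 2.0 if measure == "Ki" else ic50
    return measure, value


def _efflux_value(rng, substrate: bool, conflicting: bool) -> float:
    want_substrate = substrate != conflicting
    return rng.uniform(2.2, 20.0) if want_substrate else rng.uniform(0.2, 2.0)


def _invivo_value(rng, inhibitor: bool, conflicting: bool) -> float:
    want = inhibitor != conflicting
    return rng.uniform(1.25, 3.0) if want else rng.uniform(0.5, 1.124)


def generate_assay_records(spec: FixtureSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multi-source assay-record table plus per-compound ground truth.

    Returns ``(records, truth)``.  ``records`` has the columns the curation
    reader expects (smiles, assay_kind, probe_substrate, cell_line, measure,
    value, annotated).  ``truth`` holds the planted per-compound labels
    (is_inhibitor, is_substrate, is_allocrite) keyed by smiles.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    smiles = enumerate_smiles(spec.n_compounds)
    lo, hi = spec.n_records_per_compound

    rows = []
    truth_rows = []
    for smi in smiles:
        is_inh = bool(rng.random() < 0.5)
        is_sub = bool(rng.random() < 0.5)
        truth_rows.append({"smiles": smi, "is_inhibitor": is_inh,
                           "is_substrate": is_sub,
                           "is_allocrite": is_inh or is_sub})
        n_rec = int(rng.integers(lo, hi + 1))
        kinds = rng.choice(["invitro_inhibition", "invitro_efflux",
                            "invivo_inhibition"], size=n_rec, p=[0.5, 0.4, 0.1])
        for kind in kinds:
            conflicting = bool(rng.random() < spec.conflict_rate)
            missing = bool(rng.random() < spec.frac_missing_metadata)
            probe = str(rng.choice(_PROBES))
            cell = str(rng.choice(_CELLS))
            if kind == "invitro_inhibition":
                measure, value = _inhibition_value(rng, is_inh, conflicting)
            elif kind == "invitro_efflux":
                measure, value = "ER", _efflux_value(rng, is_sub, conflicting)
            else:
                measure, value = "AUC_ratio", _invivo_value(rng, is_inh, conflicting)
                probe = "digoxin"
            if missing:
                probe, cell = None, None
            rows.append({"smiles": smi, "assay_kind": kind,
                         "probe_substrate": probe, "cell_line": cell,
                         "measure": measure, "value": round(float(value), 6),
                         "annotated": not missing})
    records = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows).set_index("smiles")
    return records, truth


# ---------------------------------------------------------------------
# planted-signal descriptor fixtures
# ---------------------------------------------------------------------

def _block_correlated(rng, n: int, p: int, block: int, rho: float) -> np.ndarray:
    """Gaussian matrix whose columns form equicorrelated blocks of ``block``."""
    x = np.empty((n, p))
    for start in range(0, p, block):
        width = min(block, p - start)
        shared = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, width))
        x[:, start:start + width] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
    return x


def generate_signal_molecules(spec: FixtureSpec, n: int | None = None,
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Descriptor matrix with a planted class signal and corrupted labels.

    Returns ``(X, y_clean, y_noisy)``.  Columns form correlated Gaussian
    blocks (so the feature-map layout has genuine correlation structure to
    embed); the first ``signal_dims`` columns carry a class-conditional
    mean shift of ``effect_size`` standard deviations; ``y_noisy`` equals
    ``y_clean`` with labels flipped independently at ``noisy_flip_rate``.
    """
    spec.validate()
    if n is None:
        n = spec.n_compounds
    rng = np.random.default_rng(spec.seed)
    X = _block_correlated(rng, n, spec.n_descriptors, spec.block_size, spec.block_rho)
    y = (rng.random(n) < 0.5).astype(int)
    shift = spec.effect_size * (y[:, None] - 0.5)
    X[:, :spec.signal_dims] += shift
    flips = rng.random(n) < spec.noisy_flip_rate
    y_noisy = np.where(flips, 1 - y, y)
    return X, y, y_noisy
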