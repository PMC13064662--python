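"""2D molecular-descriptor feature maps (Fmaps).

A feature map turns a molecule's flat descriptor vector into a small 2D
grid image in which correlated descriptors sit close together, so that a
convolutional encoder can exploit the local correlation structure.  The
layout is learned once from a reference descriptor matrix:

1. pairwise descriptor dissimilarity 1 - |Spearman rho| over the reference
   molecules;
2. a 2D embedding of the descriptors (UMAP by default; classical MDS as a
   fully deterministic alternative);
3. a one-to-one assignment of descriptors to lattice cells minimizing the
   total squared displacement between (rescaled) embedding coordinates and
   cell centers (Hungarian algorithm), which makes the assignment a
   bijection by construction.

Rendering standardizes each descriptor with robust statistics (median/IQR
with quantile clipping) learned from the same reference matrix and writes
the scaled value to the descriptor's cell; unassigned cells stay 0.

Descriptor computation for SMILES inputs uses RDKit's 2D descriptor set
plus 2D autocorrelation, binned into the 13 conventional categories
(Property, Constitution, Fragment, Charge, Estate, MOE, Topology, Kappa,
Connectivity, Autocorr, Path, Matrix, InfoContent).  The registry is
pluggable and makes no promise about an exact descriptor count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import spearmanr

__all__ = ["FeatureMapLayout", "Fmap", "descriptor_registry",
           "compute_descriptors", "fit_layout", "render_fmap", "render_batch"]


# ---------------------------------------------------------------------
# descriptor registry (RDKit-backed)
# ---------------------------------------------------------------------

_CATEGORY_RULES = [
    ("Autocorr", ("AUTOCORR",)),
    ("Estate", ("EState", "MaxEState", "MinEState", "MaxAbsEState",
                "MinAbsEState", "VSA_EState")),
    ("MOE", ("SlogP_VSA", "SMR_VSA", "PEOE_VSA", "EState_VSA", "LabuteASA",
             "TPSA")),
    ("Charge", ("MaxPartialCharge", "MinPartialCharge", "MaxAbsPartialCharge",
                "MinAbsPartialCharge")),
    ("Fragment", ("fr_",)),
    ("Kappa", ("Kappa",)),
    ("Connectivity", ("Chi",)),
    ("Matrix", ("BCUT2D",)),
    ("InfoContent", ("Ipc", "AvgIpc", "BertzCT")),
    ("Topology", ("BalabanJ", "HallKierAlpha", "Phi")),
    ("Path", ("NumRotatableBonds", "NumBridgeheadAtoms", "NumSpiroAtoms",
              "RingCount", "NumAliphaticRings", "NumAromaticRings",
              "NumSaturatedRings", "NumAliphaticCarbocycles",
              "NumAliphaticHeterocycles", "NumAromaticCarbocycles",
              "NumAromaticHeterocycles", "NumSaturatedCarbocycles",
              "NumSaturatedHeterocycles")),
    ("Constitution", ("NumH", "NHOH", "NOCount", "Heavy", "NumAtoms",
                      "NumHetero", "NumValence", "FractionCSP3",
                      "NumAmideBonds")),
]

CATEGORIES = ("Property", "Constitution", "Fragment", "Charge", "Estate",
              "MOE", "Topology", "Kappa", "Connectivity", "Autocorr", "Path",
              "Matrix", "InfoContent")


def _categorize(name: str) -> str:
    for cat, prefixes in _CATEGORY_RULES:
        if any(name.startswith(p) or p in name for p in prefixes):
            return cat
    return "Property"


def descriptor_registry(include_autocorr: bool = True) -> dict[str, str]:
    """Name -> category for the default RDKit-backed descriptor set."""
    from rdkit.Chem import Descriptors

    registry = {name: _categorize(name) for name, _ in Descriptors.descList}
    if include_autocorr:
        for i in range(192):
            registry[f"AUTOCORR2D_{i}"] = "Autocorr"
    return registry


def compute_descriptors(smiles: str, registry: dict[str, str] | None = None,
                        ) -> pd.Series:
    """One finite value per registered descriptor for one molecule.

    Descriptors that fail or return non-finite values are NaN here and
    imputed by the layout's training median at render time.
    """
    from rdkit import Chem
    from rdkit.Chem import Descriptors, rdMolDescriptors

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable structure: {smiles!r}")
    registry = registry or descriptor_registry()
    calc = dict(Descriptors.descList)
    autocorr = None
    values = {}
    for name in registry:
        if name.startswith("AUTOCORR2D_"):
            if autocorr is None:
                try:
                    autocorr = rdMolDescriptors.CalcAUTOCORR2D(mol)
                except Exception:
                    autocorr = []
            i = int(name.split("_")[-1])
            v = autocorr[i] if i < len(autocorr) else np.nan
        else:
            try:
                v = calc[name](mol)
            except Exception:
                v = np.nan
        values[name] = float(v) if v is not None and np.isfinite(v) else np.nan
    return pd.Series(values)


# ---------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------

@dataclass
class FeatureMapLayout:
    """Bijective descriptor -> lattice-cell assignment with scaling stats."""

    descriptor_names: list[str]
    grid_shape: tuple[int, int]
    cell_of: dict[str, tuple[int, int]]
    category_of: dict[str, str] = field(default_factory=dict)
    median: np.ndarray | None = None       # per-descriptor robust center
    iqr: np.ndarray | None = None          # per-descriptor robust scale
    clip: tuple[float, float] = (-3.0, 3.0)
    scaling: str = "robust"                # "robust" | "none"
    seed: int = 0

    def validate(self) -> None:
        cells = list(self.cell_of.values())
        if len(set(cells)) != len(cells):
            raise ValueError("cell assignment is not injective")
        if set(self.cell_of) != set(self.descriptor_names):
            raise ValueError("every descriptor must be assigned a cell")
        r, c = self.grid_shape
        if any(not (0 <= i < r and 0 <= j < c) for i, j in cells):
            raise ValueError("cell outside grid")

    # -- persistence (JSON sidecar) -----------------------------------
    def to_json(self, path) -> None:
        payload = {
            "grid_shape": list(self.grid_shape),
            "scaling": self.scaling,
            "clip": list(self.clip),
            "seed": self.seed,
            "descriptors": [
                {"name": n, "row": self.cell_of[n][0], "col": self.cell_of[n][1],
                 "category": self.category_of.get(n, "Property"),
                 "median": None if self.median is None else float(self.median[i]),
                 "iqr": None if self.iqr is None else float(self.iqr[i])}
                for i, n in enumerate(self.descriptor_names)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FeatureMapLayout":
        with open(path) as fh:
            payload = json.load(fh)
        names = [d["name"] for d in payload["descriptors"]]
        med = [d["median"] for d in payload["descriptors"]]
        iqr = [d["iqr"] for d in payload["descriptors"]]
        layout = cls(
            descriptor_names=names,
            grid_shape=tuple(payload["grid_shape"]),
            cell_of={d["name"]: (d["row"], d["col"])
                     for d in payload["descriptors"]},
            category_of={d["name"]: d["category"] for d in payload["descriptors"]},
            median=None if med[0] is None else np.asarray(med, dtype=float),
            iqr=None if iqr[0] is None else np.asarray(iqr, dtype=float),
            clip=tuple(payload["clip"]),
            scaling=payload["scaling"],
            seed=payload["seed"],
        )
        layout.validate()
        return layout


def _embed(dist: np.ndarray, method: str, seed: int) -> np.ndarray:
    n = dist.shape[0]
    if method == "umap":
        import umap

        nn = min(15, n - 1)
        reducer = umap.UMAP(n_components=2, metric="precomputed",
                            n_neighbors=nn, random_state=seed, n_jobs=1)
        return np.asarray(reducer.fit_transform(dist), dtype=float)
    if method == "cmds":
        # classical (Torgerson) MDS: deterministic eigendecomposition
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (dist ** 2) @ j
        w, v = np.linalg.eigh(b)
        idx = np.argsort(w)[::-1][:2]
        coords = v[:, idx] * np.sqrt(np.maximum(w[idx], 0.0))
        # sign convention: largest-|coordinate| entry positive per axis
        for k in range(coords.shape[1]):
            pivot = np.argmax(np.abs(coords[:, k]))
            if coords[pivot, k] < 0:
                coords[:, k] *= -1
        return coords
    raise ValueError(f"unknown embedding method {method!r}")


def fit_layout(reference: pd.DataFrame | np.ndarray,
               grid_shape: tuple[int, int] | None = None,
               seed: int = 0, method: str = "umap",
               category_of: dict[str, str] | None = None,
               scaling: str = "robust",
               clip: tuple[float, float] = (-3.0, 3.0)) -> FeatureMapLayout:
    """Learn a descriptor -> lattice layout from a reference matrix.

    ``reference`` is molecules x descriptors.  Distances are
    1 - |Spearman rho|; descriptors are embedded in 2D and assigned
    one-to-one to lattice cells by minimum total squared displacement.
    Deterministic given ``seed``.
    """
    if isinstance(reference, pd.DataFrame):
        names = list(reference.columns)
        x = reference.to_numpy(dtype=float)
    else:
        x = np.asarray(reference, dtype=float)
        names = [f"d{i}" for i in range(x.shape[1])]
    if x.shape[0] < 2:
        raise ValueError("need at least 2 reference molecules")
    p = x.shape[1]
    if grid_shape is None:
        side = int(np.ceil(np.sqrt(p)))
        grid_shape = (side, side)
    rows, cols = grid_shape
    if rows * cols < p:
        raise ValueError(f"grid {grid_shape} cannot hold {p} descriptors")

    med = np.nanmedian(x, axis=0)
    x_imp = np.where(np.isfinite(x), x, med)
    if not np.all(np.isfinite(x_imp)):
        raise ValueError("reference contains all-NaN descriptor columns")
    q25, q75 = np.percentile(x_imp, [25, 75], axis=0)
    iqr = np.where(q75 - q25 > 0, q75 - q25, 1.0)
    if np.all(x_imp.std(axis=0) == 0):
        raise ValueError("reference matrix is constant")

    with np.errstate(invalid="ignore", divide="ignore"):
        rho = spearmanr(x_imp, axis=0).statistic
    # constant columns yield NaN correlations: treat as uncorrelated
    rho = np.atleast_2d(np.nan_to_num(rho, nan=0.0))
    dist = 1.0 - np.abs(rho)
    np.fill_diagonal(dist, 0.0)

    coords = _embed(dist, method, seed)
    # rescale embedding into the grid's bounding box, then solve the
    # assignment problem against cell centers
    span = coords.max(axis=0) - coords.min(axis=0)
    span[span == 0] = 1.0
    scaled = (coords - coords.min(axis=0)) / span
    scaled = scaled * (np.array([rows, cols]) - 1)
    cells = np.array([(i, j) for i in range(rows) for j in range(cols)],
                     dtype=float)
    cost = ((scaled[:, None, :] - cells[None, :, :]) ** 2).sum(axis=2)
    ri, ci = linear_sum_assignment(cost)
    order = np.argsort(ri)  # descriptors in registry order (row-major ties)
    cell_of = {names[d]: (int(cells[c, 0]), int(cells[c, 1]))
               for d, c in zip(ri[order], ci[order])}

    layout = FeatureMapLayout(
        descriptor_names=names, grid_shape=grid_shape, cell_of=cell_of,
        category_of=category_of or {}, median=med, iqr=iqr, clip=clip,
        scaling=scaling, seed=seed)
    layout.validate()
    return layout


# ---------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------

@dataclass
class Fmap:
    values: np.ndarray
    molecule_id: str | int | None
    layout: FeatureMapLayout


def _scale_vector(vector: np.ndarray, layout: FeatureMapLayout) -> np.ndarray:
    v = np.asarray(vector, dtype=float)
    if layout.median is not None:
        v = np.where(np.isfinite(v), v, layout.median)
    if layout.scaling == "robust":
        v = (v - layout.median) / layout.iqr
        v = np.clip(v, *layout.clip)
    elif layout.scaling != "none":
        raise ValueError(f"unknown scaling {layout.scaling!r}")
    return v


def render_fmap(vector, layout: FeatureMapLayout,
                molecule_id=None) -> Fmap:
    """Place a (scaled) descriptor vector onto the layout's grid."""
    if isinstance(vector, pd.Series):
        vector = vector.reindex(layout.descriptor_names).to_numpy(dtype=float)
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (len(layout.descriptor_names),):
        raise ValueError(
            f"vector length {vector.shape} does not match layout "
            f"({len(layout.descriptor_names)} descriptors)")
    scaled = _scale_vector(vector, layout)
    grid = np.zeros(layout.grid_shape)
    for i, name in enumerate(layout.descriptor_names):
        r, c = layout.cell_of[name]
        grid[r, c] = scaled[i]
    return Fmap(grid, molecule_id, layout)


def render_batch(matrix, layout: FeatureMapLayout) -> np.ndarray:
    """Render n molecules to an (n, rows, cols) array, order preserved."""
    if isinstance(matrix, pd.DataFrame):
        matrix = matrix[layout.descriptor_names].to_numpy(dtype=float)
    matrix = np.asarray(matrix, dtype=float)
    out = np.zeros((matrix.shape[0],) + tuple(layout.grid_shape))
    idx = np.array([layout.cell_of[n] for n in layout.descriptor_names])
    scaled = np.vstack([_scale_vector(row, layout) for row in matrix])
    out[:, idx[:, 0], idx[:, 1]] = scaled
    return out
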