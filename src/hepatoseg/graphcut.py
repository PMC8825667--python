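"""Four-term graph-cut tumor segmentation inside a liver mask.

The energy of a binary labeling (object = hypodense tumor, background =
healthy parenchyma) is

    E = E_data + E_enhance + E_shape + E_boundary

with

* E_data     — negative log posterior odds from per-class intensity models,
* E_enhance  — -ln vesselness, added to the *background* unary so enhanced
               vessels are cheap to keep out of the tumor label,
* E_shape    — -ln blobness, added to the *object* unary so isotropic dark
               structures are cheap to label tumor,
* E_boundary — pairwise contrast kernel 1 / (1 + (Ip - Iq)^2 / (2 sigma^2)),
               divided by the inter-voxel distance on anisotropic grids.

The pairwise terms are submodular, so the global minimizer is found by
max-flow/min-cut.  Capacities are scaled to integers for
``scipy.sparse.csgraph.maximum_flow`` and the partition is recovered by
reachability in the residual graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from .core import LESION, VESSEL, Mask, Volume

_FLOOR = 1e-6


@dataclass
class IntensityModel:
    """Per-class 1D intensity likelihoods over the 0-255 range.

    Default is a Gaussian per class; a histogram option (64 bins, floored)
    is available for non-Gaussian tissue distributions.  Both densities are
    floored at 1e-6 so log-likelihood costs stay finite.
    """

    kind: str = "gaussian"
    object_params: dict = field(default_factory=dict)
    background_params: dict = field(default_factory=dict)
    source: str = "unspecified"

    def _pdf(self, params: dict, intensities: np.ndarray) -> np.ndarray:
        x = np.asarray(intensities, dtype=np.float64)
        if self.kind == "gaussian":
            mu, sd = params["mu"], max(params["sigma"], 1e-3)
            p = np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
        elif self.kind == "histogram":
            edges = params["edges"]
            dens = params["density"]
            idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(dens) - 1)
            p = dens[idx]
        else:
            raise ValueError(f"unknown model kind {self.kind!r}")
        return np.maximum(p, _FLOOR)

    def p_object(self, intensities) -> np.ndarray:
        return self._pdf(self.object_params, intensities)

    def p_background(self, intensities) -> np.ndarray:
        return self._pdf(self.background_params, intensities)


def fit_intensity_models(volume: Volume, liver: Mask | np.ndarray,
                         tumor_examples: Mask | np.ndarray,
                         kind: str = "gaussian") -> IntensityModel:
    """Fit tumor (object) and healthy-liver (background) intensity densities.

    ``tumor_examples`` marks training lesion voxels; background is the rest
    of the liver mask.
    """
    liv = liver.binary() if isinstance(liver, Mask) else np.asarray(liver).astype(bool)
    tum = (tumor_examples.binary() if isinstance(tumor_examples, Mask)
           else np.asarray(tumor_examples).astype(bool))
    obj_vals = volume.data[tum & liv] if (tum & liv).any() else volume.data[tum]
    bg_vals = volume.data[liv & ~tum]
    if obj_vals.size == 0 or bg_vals.size == 0:
        raise ValueError("both intensity classes must be non-empty")

    def params(vals):
        if kind == "gaussian":
            return {"mu": float(vals.mean()), "sigma": float(vals.std())}
        edges = np.linspace(0.0, 255.0, 65)
        hist, _ = np.histogram(vals, bins=edges, density=True)
        return {"edges": edges, "density": np.maximum(hist, _FLOOR)}

    return IntensityModel(kind=kind, object_params=params(obj_vals),
                          background_params=params(bg_vals), source="mask-fit")


def data_term(volume: Volume, model: IntensityModel):
    """Negative log posterior-odds unary costs, per voxel.

    cost(object)     = -ln[P(I|O) / (P(I|O)+P(I|B))]
    cost(background) = -ln[P(I|B) / (P(I|O)+P(I|B))]
    """
    po = model.p_object(volume.data)
    pb = model.p_background(volume.data)
    tot = po + pb
    return -np.log(po / tot), -np.log(pb / tot)


_OFFSETS_6 = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
_OFFSETS_26 = [(dx, dy, dz)
               for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
               if (dx, dy, dz) > (0, 0, 0)]


def neighbor_offsets(connectivity: int):
    if connectivity == 6:
        return list(_OFFSETS_6)
    if connectivity == 26:
        return list(_OFFSETS_26)
    raise ValueError("connectivity must be 6 or 26")


def boundary_weight(delta_i: np.ndarray, sigma: float) -> np.ndarray:
    """Contrast kernel 1 / (1 + (Ip - Iq)^2 / (2 sigma^2)), in (0, 1]."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return 1.0 / (1.0 + np.asarray(delta_i, dtype=np.float64) ** 2 / (2.0 * sigma**2))


def boundary_term(volume: Volume, sigma: float, connectivity: int = 6,
                  distance_weighting: bool = True):
    """Pairwise weights for every neighbor pair in the full grid.

    Returns a list of (offset, weight_array) where ``weight_array[p]`` is the
    weight between voxel p and p+offset (valid on the overlapping region).
    """
    weights = []
    sp = np.asarray(volume.spacing)
    for off in neighbor_offsets(connectivity):
        sl_a = tuple(slice(None, -o) if o else slice(None) for o in off)
        sl_b = tuple(slice(o, None) if o else slice(None) for o in off)
        delta = volume.data[sl_a] - volume.data[sl_b]
        w = boundary_weight(delta, sigma)
        if distance_weighting:
            w = w / float(np.linalg.norm(sp * np.asarray(off)))
        weights.append((off, w))
    return weights


@dataclass
class EnergyField:
    """Graph-cut problem restricted to an ROI: unaries + pairwise weights."""

    roi: np.ndarray                  # boolean grid, nodes of the graph
    unary_object: np.ndarray         # cost per roi voxel, shape (n,)
    unary_background: np.ndarray
    pair_i: np.ndarray               # roi-node indices, edge endpoints
    pair_j: np.ndarray
    pair_w: np.ndarray               # pairwise weight per edge (>0)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    terms: dict = field(default_factory=dict)   # per-term unaries, bookkeeping

    @property
    def n_nodes(self) -> int:
        return int(self.unary_object.size)

    def energy_of(self, labeling: np.ndarray) -> float:
        """Total energy of a binary labeling (1 = object) over roi nodes."""
        lab = np.asarray(labeling).astype(bool)
        e = float(self.unary_object[lab].sum() + self.unary_background[~lab].sum())
        cut = lab[self.pair_i] != lab[self.pair_j]
        return e + float(self.pair_w[cut].sum())


@dataclass
class TermWeights:
    enhance: float = 1.0   # vessel energy coefficient (background unary)
    shape: float = 1.0     # blob energy coefficient (object unary)
    boundary: float = 1.0  # pairwise coefficient


@dataclass
class Segmentation:
    mask: Mask                      # tumor (and possibly vessel) labels
    energy: float                   # energy attained by the labeling
    component_volumes_ml: list[float] = field(default_factory=list)

    def tumor(self) -> np.ndarray:
        return self.mask.data == LESION


def assemble_energy(volume: Volume, liver: Mask | np.ndarray,
                    model: IntensityModel,
                    vessel_energy: np.ndarray | None = None,
                    blob_energy: np.ndarray | None = None,
                    weights: TermWeights | None = None,
                    sigma: float = 10.0,
                    connectivity: int = 6,
                    eligible: np.ndarray | None = None) -> EnergyField:
    """Build the four-term energy field over the liver ROI.

    ``eligible`` (e.g. liver minus enhanced vessels) restricts the graph
    nodes further than the liver mask alone.
    """
    liv = liver.binary() if isinstance(liver, Mask) else np.asarray(liver).astype(bool)
    roi = liv if eligible is None else (liv & np.asarray(eligible).astype(bool))
    w = weights or TermWeights()

    for name, m in (("vessel_energy", vessel_energy), ("blob_energy", blob_energy)):
        if m is not None and m.shape != volume.data.shape:
            raise ValueError(f"{name} shape {m.shape} != volume shape {volume.data.shape}")

    cost_obj, cost_bg = data_term(volume, model)
    u_obj = cost_obj.copy()
    u_bg = cost_bg.copy()
    terms = {"data_object": cost_obj[roi], "data_background": cost_bg[roi]}
    if blob_energy is not None and w.shape != 0:
        u_obj = u_obj + w.shape * blob_energy
        terms["shape_object"] = w.shape * blob_energy[roi]
    if vessel_energy is not None and w.enhance != 0:
        u_bg = u_bg + w.enhance * vessel_energy
        terms["enhance_background"] = w.enhance * vessel_energy[roi]

    idx = -np.ones(volume.data.shape, dtype=np.int64)
    idx[roi] = np.arange(int(roi.sum()))

    pi, pj, pw = [], [], []
    for off, warr in boundary_term(volume, sigma, connectivity):
        sl_a = tuple(slice(None, -o) if o else slice(None) for o in off)
        sl_b = tuple(slice(o, None) if o else slice(None) for o in off)
        ia, ib = idx[sl_a], idx[sl_b]
        valid = (ia >= 0) & (ib >= 0)
        pi.append(ia[valid])
        pj.append(ib[valid])
        pw.append(w.boundary * warr[valid])

    return EnergyField(
        roi=roi,
        unary_object=u_obj[roi],
        unary_background=u_bg[roi],
        pair_i=np.concatenate(pi) if pi else np.empty(0, np.int64),
        pair_j=np.concatenate(pj) if pj else np.empty(0, np.int64),
        pair_w=np.concatenate(pw) if pw else np.empty(0, np.float64),
        spacing=volume.spacing,
        terms=terms,
    )


_CAP_SCALE = 100_000  # float -> integer capacity scaling for maximum_flow


def min_cut_labeling(field: EnergyField) -> np.ndarray:
    """Globally minimal binary labeling of an :class:`EnergyField`.

    Source side = object.  Edge capacities: s->p carries the background
    unary, p->t the object unary, p<->q the pairwise weight, so any s-t cut
    pays exactly the energy of the corresponding labeling.
    """
    n = field.n_nodes
    if n == 0:
        return np.zeros(0, dtype=bool)
    if np.any(field.pair_w < 0):
        raise ValueError("negative pairwise weight: energy not submodular")
    s, t = n, n + 1

    def cap(x):
        c = np.rint(np.asarray(x, dtype=np.float64) * _CAP_SCALE)
        return np.clip(c, 0, np.iinfo(np.int64).max // 4).astype(np.int64)

    rows = np.concatenate([np.full(n, s), np.arange(n), field.pair_i, field.pair_j])
    cols = np.concatenate([np.arange(n), np.full(n, t), field.pair_j, field.pair_i])
    caps = np.concatenate([cap(field.unary_background), cap(field.unary_object),
                           cap(field.pair_w), cap(field.pair_w)])
    graph = csr_matrix((caps, (rows, cols)), shape=(n + 2, n + 2))
    res = maximum_flow(graph, s, t)
    residual = graph - res.flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    order = breadth_first_order(residual, s, directed=True, return_predecessors=False)
    labeling = np.zeros(n, dtype=bool)
    labeling[order[order < n]] = True
    return labeling


def min_cut_segment(field: EnergyField) -> Segmentation:
    """Run the min-cut and package the result as a labeled Segmentation."""
    labeling = min_cut_labeling(field)
    mask = np.zeros(field.roi.shape, dtype=np.uint8)
    mask[field.roi] = np.where(labeling, LESION, 0)
    seg_mask = Mask(mask, field.spacing)
    lab, n_comp = ndi.label(mask == LESION)
    vox_ml = float(np.prod(field.spacing)) / 1000.0
    volumes = [float((lab == k).sum()) * vox_ml for k in range(1, n_comp + 1)]
    return Segmentation(mask=seg_mask, energy=field.energy_of(labeling),
                        component_volumes_ml=volumes)


def remove_vessels(segmentation: Segmentation, vessel_map: np.ndarray,
                   threshold: float) -> Segmentation:
    """Relabel tumor voxels with vesselness >= threshold as vessel.

    Enhanced vessels are the dominant false-positive source for hypodense
    tumor detection; this excises them from the tumor label.  With
    threshold = +inf the segmentation is unchanged; with threshold = 0 no
    voxel stays tumor-eligible.
    """
    vm = np.asarray(vessel_map)
    if vm.shape != segmentation.mask.shape:
        raise ValueError("vessel map not aligned to segmentation grid")
    data = segmentation.mask.data.copy()
    kill = (vm >= threshold)
    data[(data == LESION) & kill] = VESSEL
    new_mask = Mask(data, segmentation.mask.spacing)
    vox_ml = float(np.prod(segmentation.mask.spacing)) / 1000.0
    lab, n_comp = ndi.label(data == LESION)
    volumes = [float((lab == k).sum()) * vox_ml for k in range(1, n_comp + 1)]
    return Segmentation(mask=new_mask, energy=segmentation.energy,
                        component_volumes_ml=volumes)


def vessel_eligible_mask(liver: np.ndarray, vessel_response: np.ndarray,
                         threshold: float) -> np.ndarray:
    """Liver voxels below the vesselness threshold (pre-cut vessel removal)."""
    return np.asarray(liver).astype(bool) & ~(np.asarray(vessel_response) >= threshold)
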