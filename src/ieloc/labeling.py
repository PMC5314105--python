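"""Anatomical and atlas-based labeling of contacts via spherical ROIs.

Each contact gets a spherical region of interest (radius 3.5 mm for SEEG,
5 mm for ECoG).  The fraction of ROI voxels carrying any nonzero area label
is the *inclusion* probability, its complement the *exclusion*; only if
inclusion exceeds exclusion is the contact called gray matter, and it is
then assigned the area holding the largest voxel fraction of the ROI, with
that fraction as the reported probability.  The same rule labels contacts
against template-space atlases (Brodmann areas, functional networks) after
an affine transform to MNI space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import ElectrodeSet
from .registration import AffineTransform
from .volumes import LabelLUT, Volume3D, voxel_to_world, world_to_voxel

ROI_RADIUS_SEEG = 3.5
ROI_RADIUS_ECOG = 5.0


@dataclass
class SphereROI:
    center: np.ndarray            # world mm
    radius: float
    voxels: np.ndarray            # (n, 3) indices on the reference grid


@dataclass
class LabelResult:
    contact_id: str
    tissue_class: str             # "gray" | "white/unknown"
    area: str | None
    probability: float
    atlas: str
    inclusion: float


def make_roi(center, radius: float, grid: Volume3D) -> SphereROI:
    """Spherical ROI by center-in-sphere voxel membership on ``grid``."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center, dtype=float)
    vs = grid.voxel_sizes
    ctr_vox = world_to_voxel(grid, center)
    lo = np.floor(ctr_vox - radius / vs - 1).astype(int)
    hi = np.ceil(ctr_vox + radius / vs + 1).astype(int) + 1
    lo_c = np.maximum(lo, 0)
    hi_c = np.minimum(hi, np.asarray(grid.shape))
    if np.any(hi_c <= lo_c):
        raise ValueError("ROI lies entirely outside the volume grid")
    idx = np.stack(np.meshgrid(*[np.arange(lo_c[i], hi_c[i]) for i in range(3)],
                               indexing="ij"), -1).reshape(-1, 3)
    world = voxel_to_world(grid, idx.astype(float))
    inside = np.linalg.norm(world - center, axis=1) <= radius
    if not inside.any():
        raise ValueError("ROI contains no voxel centers inside the grid")
    return SphereROI(center=center, radius=radius, voxels=idx[inside])


def label_roi(roi: SphereROI, parcellation: Volume3D, lut: LabelLUT,
              contact_id: str = "", atlas: str = "parcellation") -> LabelResult:
    """Inclusion/exclusion + maximum-probability area assignment."""
    labels = parcellation.data[roi.voxels[:, 0], roi.voxels[:, 1],
                               roi.voxels[:, 2]].astype(int)
    n = len(labels)
    inclusion = float(np.count_nonzero(labels)) / n
    exclusion = 1.0 - inclusion
    if inclusion <= exclusion:
        return LabelResult(contact_id, "white/unknown", None, inclusion,
                           atlas, inclusion)
    vals, counts = np.unique(labels[labels > 0], return_counts=True)
    # maximal voxel fraction; ties break to the smaller label index
    best = vals[np.argmax(counts)]
    prob = float(counts.max()) / n
    return LabelResult(contact_id, "gray", lut.name(int(best)), prob, atlas,
                       inclusion)


def label_contacts(contacts: ElectrodeSet, parcellation: Volume3D,
                   lut: LabelLUT, radius: float,
                   atlas: str = "parcellation") -> list[LabelResult]:
    """Label every contact in native space; results also attach to contacts."""
    out = []
    for c in contacts:
        roi = make_roi(c.position, radius, parcellation)
        res = label_roi(roi, parcellation, lut, contact_id=c.id, atlas=atlas)
        c.labels.append(res)
        out.append(res)
    return out


def contacts_to_mni(contacts: ElectrodeSet, affine: AffineTransform,
                    template: Volume3D | None = None,
                    radius: float = ROI_RADIUS_SEEG,
                    ) -> tuple[ElectrodeSet, list[SphereROI | None]]:
    """Map contact centers to standard space; regenerate ROIs on the template.

    Centers falling outside the template bounding box are flagged and get no
    ROI (a warning is emitted rather than an error).
    """
    out = contacts.copy()
    rois: list[SphereROI | None] = []
    for c in out:
        c.mni = affine.apply(c.position)[0]
        roi = None
        if template is not None:
            vox = world_to_voxel(template, c.mni)
            if np.any(vox < -0.5) or np.any(
                    vox > np.asarray(template.shape) - 0.5):
                c.mni_out_of_field = True
                warnings.warn(f"contact {c.id} maps outside the template",
                              stacklevel=2)
            else:
                roi = make_roi(c.mni, radius, template)
        rois.append(roi)
    return out, rois


def atlas_label(contacts: ElectrodeSet, atlas_vol: Volume3D, lut: LabelLUT,
                atlas_name: str, radius: float = ROI_RADIUS_SEEG,
                ) -> list[LabelResult]:
    """Label MNI-space contacts against a template-space atlas volume."""
    out = []
    for c in contacts:
        if c.mni is None:
            raise ValueError(f"contact {c.id} has no MNI coordinate; run "
                             "contacts_to_mni first")
        if c.mni_out_of_field:
            res = LabelResult(c.id, "white/unknown", None, 0.0, atlas_name, 0.0)
        else:
            roi = make_roi(c.mni, radius, atlas_vol)
            res = label_roi(roi, atlas_vol, lut, contact_id=c.id,
                            atlas=atlas_name)
        c.labels.append(res)
        out.append(res)
    return out


def contacts_table(contacts: ElectrodeSet,
                   columns: list[str] | None = None) -> pd.DataFrame:
    """One row per contact: identity, native + MNI coordinates, labels."""
    atlas_names: list[str] = []
    for c in contacts:
        for r in c.labels:
            if r.atlas not in atlas_names:
                atlas_names.append(r.atlas)
    rows = []
    for c in contacts:
        row: dict = {
            "electrode": c.electrode, "contact": c.index,
            "x": c.position[0], "y": c.position[1], "z": c.position[2],
            "mni_x": c.mni[0] if c.mni is not None else np.nan,
            "mni_y": c.mni[1] if c.mni is not None else np.nan,
            "mni_z": c.mni[2] if c.mni is not None else np.nan,
            "padded": c.padded,
        }
        by_atlas = {r.atlas: r for r in c.labels}
        primary = by_atlas.get("parcellation") or (
            c.labels[0] if c.labels else None)
        row["tissue"] = primary.tissue_class if primary else ""
        row["area"] = (primary.area or "") if primary else ""
        row["probability"] = primary.probability if primary else np.nan
        for a in atlas_names:
            if a == (primary.atlas if primary else None):
                continue
            r = by_atlas.get(a)
            row[f"{a}_area"] = (r.area or "") if r else ""
            row[f"{a}_probability"] = r.probability if r else np.nan
        rows.append(row)
    base_cols = ["electrode", "contact", "x", "y", "z", "mni_x", "mni_y",
                 "mni_z", "tissue", "area", "probability", "padded"]
    df = pd.DataFrame(rows, columns=None if rows else base_cols)
    if columns is not None:
        df = df[columns]
    return df


def export_table(contacts: ElectrodeSet, path,
                 columns: list[str] | None = None) -> pd.DataFrame:
    """Write the contact summary as a TSV file; returns the DataFrame."""
    df = contacts_table(contacts, columns=columns)
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")
    return df
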