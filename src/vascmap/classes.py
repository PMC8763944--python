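"""Tissue class codes shared across the package.

Label volumes are unsigned-integer maps with one code per voxel. Code 0
marks extracranial ("excluded") voxels, which never contribute to
training, prediction or evaluation. Codes 1-5 are the intracranial
tissue classes of the vascular-anatomical map.
"""

from __future__ import annotations

EXCLUDED = 0
ARTERY = 1
VEIN = 2
BRAIN = 3
CSF = 4
EV = 5  # embolized vessel

#: tissue classes, in code order (excluded is not a tissue)
TISSUE_CLASSES: tuple[int, ...] = (ARTERY, VEIN, BRAIN, CSF, EV)

CLASS_NAMES: dict[int, str] = {
    EXCLUDED: "excluded",
    ARTERY: "artery",
    VEIN: "vein",
    BRAIN: "brain",
    CSF: "csf",
    EV: "ev",
}

NAME_TO_CODE: dict[str, int] = {v: k for k, v in CLASS_NAMES.items()}

#: MR contrast channel order fed to every model; fixed package-wide
CONTRASTS: tuple[str, str, str] = ("tof", "t1c", "t2")
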