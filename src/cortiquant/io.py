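"""File I/O: annotation CSVs, observation CSVs, images, YAML configs.

Annotation CSV schema (one row per follicle; sections without follicles
still contribute one row with an empty ``follicle_id`` so their area is
never lost):

    fragment_id, arm, condition, section_id, analysis_role,
    section_area_mm2, follicle_id, stage, granulosa_disorganized,
    ooplasm_shrunken, oocyte_pyknotic, ki67_pos_granulosa_count
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, DataError
from .follicles import FollicleAnnotation, FragmentRecord, SectionRecord
from .synth import StudyGenConfig

ANNOTATION_COLUMNS = [
    "fragment_id", "arm", "condition", "section_id", "analysis_role",
    "section_area_mm2", "follicle_id", "stage", "granulosa_disorganized",
    "ooplasm_shrunken", "oocyte_pyknotic", "ki67_pos_granulosa_count",
]


def fragments_to_frame(fragments: list[FragmentRecord]) -> pd.DataFrame:
    rows = []
    for frag in fragments:
        for sec in frag.sections:
            base = {
                "fragment_id": frag.fragment_id,
                "arm": frag.arm,
                "condition": frag.condition,
                "section_id": sec.section_id,
                "analysis_role": sec.analysis_role,
                "section_area_mm2": sec.area_mm2,
            }
            if not sec.follicles:
                rows.append({**base, "follicle_id": "", "stage": "",
                             "granulosa_disorganized": False,
                             "ooplasm_shrunken": False,
                             "oocyte_pyknotic": False,
                             "ki67_pos_granulosa_count": 0})
                continue
            for f in sec.follicles:
                rows.append({
                    **base,
                    "follicle_id": f.follicle_id,
                    "stage": f.stage,
                    "granulosa_disorganized": f.granulosa_disorganized,
                    "ooplasm_shrunken": f.ooplasm_shrunken,
                    "oocyte_pyknotic": f.oocyte_pyknotic,
                    "ki67_pos_granulosa_count": f.ki67_pos_granulosa_count,
                })
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def frame_to_fragments(df: pd.DataFrame) -> list[FragmentRecord]:
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"annotation table lacks columns: {missing}")
    fragments: dict[str, FragmentRecord] = {}
    sections: dict[tuple[str, str], SectionRecord] = {}
    for row in df.itertuples(index=False):
        frag = fragments.get(row.fragment_id)
        if frag is None:
            frag = FragmentRecord(
                fragment_id=str(row.fragment_id),
                arm=str(row.arm),
                condition=str(row.condition),
            )
            fragments[row.fragment_id] = frag
        key = (row.fragment_id, row.section_id)
        sec = sections.get(key)
        if sec is None:
            sec = SectionRecord(
                section_id=str(row.section_id),
                area_mm2=float(row.section_area_mm2),
                analysis_role=str(row.analysis_role),
            )
            sections[key] = sec
            frag.sections.append(sec)
        fid = row.follicle_id
        if fid is None or (isinstance(fid, float) and np.isnan(fid)) or fid == "":
            continue  # empty-section placeholder row
        sec.follicles.append(
            FollicleAnnotation(
                follicle_id=str(fid),
                stage=str(row.stage),
                granulosa_disorganized=bool(row.granulosa_disorganized),
                ooplasm_shrunken=bool(row.ooplasm_shrunken),
                oocyte_pyknotic=bool(row.oocyte_pyknotic),
                ki67_pos_granulosa_count=int(row.ki67_pos_granulosa_count),
            )
        )
    return list(fragments.values())


def write_annotations(fragments: list[FragmentRecord], path) -> int:
    df = fragments_to_frame(fragments)
    df.to_csv(path, index=False)
    return len(df)


def read_annotations(path) -> list[FragmentRecord]:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    return frame_to_fragments(df)


def save_image(path, arr) -> None:
    iio.imwrite(Path(path), np.asarray(arr))


def load_image(path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]  # drop alpha
    return arr


def save_mask(path, mask) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def load_mask(path) -> np.ndarray:
    return iio.imread(Path(path)) > 127


def study_config_from_dict(data: dict) -> StudyGenConfig:
    """Build a study config from a plain mapping (YAML-friendly).

    ``arm_condition_effects`` may be given as a nested mapping
    ``{arm: {condition: shift}}``.
    """
    data = dict(data)
    effects = data.get("arm_condition_effects")
    if isinstance(effects, dict) and effects:
        first = next(iter(effects.values()))
        if isinstance(first, dict):
            data["arm_condition_effects"] = {
                (arm, cond): float(v)
                for arm, sub in effects.items()
                for cond, v in sub.items()
            }
    for key in ("arms", "conditions"):
        if key in data:
            data[key] = tuple(data[key])
    try:
        return StudyGenConfig(**data)
    except TypeError as exc:
        raise ConfigError(f"invalid study config: {exc}") from exc


def load_study_config(path) -> StudyGenConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("study config must be a YAML mapping")
    return study_config_from_dict(data)


def dump_study_config(cfg: StudyGenConfig, path) -> None:
    effects: dict[str, dict[str, float]] = {}
    for (arm, cond), v in cfg.arm_condition_effects.items():
        effects.setdefault(arm, {})[cond] = float(v)
    data = {
        "arms": list(cfg.arms),
        "conditions": list(cfg.conditions),
        "punches_per_condition": cfg.punches_per_condition,
        "density_sections_per_punch": cfg.density_sections_per_punch,
        "proliferation_sections_per_punch": cfg.proliferation_sections_per_punch,
        "section_area_mm2": cfg.section_area_mm2,
        "baseline_log_density": cfg.baseline_log_density,
        "arm_condition_effects": effects,
        "fragment_sd": cfg.fragment_sd,
        "residual_sd": cfg.residual_sd,
        "p_degenerated": dict(cfg.p_degenerated),
        "p_proliferative": dict(cfg.p_proliferative),
        "p_transitional": cfg.p_transitional,
        "seed": cfg.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
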