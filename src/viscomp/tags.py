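"""Object-annotation predictors of perceived complexity.

Images annotated with VOC-style bounding-box tags can be scored without
looking at a single pixel: the class of the largest ("central") object, the
classes present in the background, and plain tag counts all carry
complexity information.  This module builds per-class complexity tables
from rated, tagged images and turns them into per-image predictions, plus
presence/count vectorisations for downstream regression.

Coordinates are 0-based, half-open: bbox = (xmin, ymin, xmax, ymax).
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "ObjectTag",
    "ClassComplexityTable",
    "central_object",
    "class_complexity_table",
    "predict_from_tags",
    "vectorize_tags",
    "read_voc_xml",
    "read_tags_json",
    "write_tags_json",
    "TAG_METHODS",
]

TAG_METHODS = ("biggest", "all_sum", "all_mean", "background_sum", "background_mean", "tag_count")


@dataclass(frozen=True)
class ObjectTag:
    """One annotated object: image, class, and half-open pixel bounding box."""

    image_id: str
    class_name: str
    bbox: tuple[int, int, int, int]  # (xmin, ymin, xmax, ymax)

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.bbox
        if not (xmax > xmin and ymax > ymin):
            raise ValidationError(f"degenerate bbox {self.bbox} for {self.image_id!r}")

    @property
    def area(self) -> int:
        xmin, ymin, xmax, ymax = self.bbox
        return (xmax - xmin) * (ymax - ymin)


@dataclass
class ClassComplexityTable:
    """Per-class mean ratings of the images containing that class.

    ``anywhere`` covers every image containing the class; the images split
    disjointly into ``central`` (class is the largest object) and
    ``background`` (class present but not largest), so the anywhere mean is
    exactly the image-count-weighted mean of the other two cells.  Cells
    with no images are NaN and listed in ``empty_cells``.
    """

    frame: pd.DataFrame  # index=class, columns: anywhere/central/background means + n_* counts
    global_mean: float

    @property
    def empty_cells(self) -> list[tuple[str, str]]:
        out = []
        for cls, row in self.frame.iterrows():
            for cell in ("central", "background"):
                if row[f"n_{cell}"] == 0:
                    out.append((cls, cell))
        return out

    def mean_of(self, class_name: str, cell: str = "anywhere") -> float:
        if class_name not in self.frame.index:
            return self.global_mean
        value = self.frame.loc[class_name, f"mean_{cell}"]
        return self.global_mean if pd.isna(value) else float(value)


def _group_by_image(tags: Iterable[ObjectTag]) -> dict[str, list[ObjectTag]]:
    grouped: dict[str, list[ObjectTag]] = {}
    for tag in tags:
        grouped.setdefault(tag.image_id, []).append(tag)
    return grouped


def central_object(tags: Sequence[ObjectTag]) -> ObjectTag:
    """The tag with the largest bounding-box area; ties break by file order."""
    if not tags:
        raise ValidationError("central_object needs at least one tag")
    best = tags[0]
    for tag in tags[1:]:
        if tag.area > best.area:
            best = tag
    return best


def class_complexity_table(
    tags: Iterable[ObjectTag], ratings: Mapping[str, float]
) -> ClassComplexityTable:
    """Per-class mean complexity of images containing the class.

    For every image the largest object defines the central class; all other
    classes present in the image count as background for that image.
    """
    grouped = _group_by_image(tags)
    rows: dict[str, dict[str, list[float]]] = {}
    for image_id, image_tags in grouped.items():
        if image_id not in ratings:
            raise ValidationError(f"image {image_id!r} is tagged but has no rating")
        rating = float(ratings[image_id])
        central_cls = central_object(image_tags).class_name
        classes = {t.class_name for t in image_tags}
        for cls in classes:
            cells = rows.setdefault(cls, {"central": [], "background": []})
            cells["central" if cls == central_cls else "background"].append(rating)

    records = []
    for cls, cells in sorted(rows.items()):
        central = cells["central"]
        background = cells["background"]
        everything = central + background
        records.append(
            {
                "class_name": cls,
                "mean_anywhere": float(np.mean(everything)),
                "mean_central": float(np.mean(central)) if central else np.nan,
                "mean_background": float(np.mean(background)) if background else np.nan,
                "n_anywhere": len(everything),
                "n_central": len(central),
                "n_background": len(background),
            }
        )
    frame = pd.DataFrame.from_records(records).set_index("class_name") if records else pd.DataFrame(
        columns=[
            "mean_anywhere", "mean_central", "mean_background",
            "n_anywhere", "n_central", "n_background",
        ]
    )
    rated_images = [float(ratings[i]) for i in grouped]
    global_mean = float(np.mean(rated_images)) if rated_images else float("nan")
    return ClassComplexityTable(frame=frame, global_mean=global_mean)


def predict_from_tags(
    tags: Iterable[ObjectTag],
    table: ClassComplexityTable,
    method: str,
    class_cell: str = "anywhere",
) -> dict[str, float]:
    """Predict each image's complexity from its tags and a class table.

    Methods: ``biggest`` (mean rating of images containing the central
    object's class), ``all_sum``/``all_mean`` (sum/mean of per-class means
    over the classes present), ``background_sum``/``background_mean`` (same
    over the non-central classes, using the background cell), ``tag_count``
    (number of tags).  Classes unseen in the table fall back to the global
    mean rating.  ``class_cell`` selects which cell the all_* methods read.
    """
    if method not in TAG_METHODS:
        raise ValidationError(f"unknown method {method!r}; choose from {TAG_METHODS}")
    out: dict[str, float] = {}
    for image_id, image_tags in _group_by_image(tags).items():
        central_cls = central_object(image_tags).class_name
        classes = sorted({t.class_name for t in image_tags})
        if method == "tag_count":
            out[image_id] = float(len(image_tags))
        elif method == "biggest":
            out[image_id] = table.mean_of(central_cls, "anywhere")
        elif method in ("all_sum", "all_mean"):
            values = [table.mean_of(cls, class_cell) for cls in classes]
            out[image_id] = float(np.sum(values) if method == "all_sum" else np.mean(values))
        else:  # background_sum / background_mean
            bg = [cls for cls in classes if cls != central_cls]
            values = [table.mean_of(cls, "background") for cls in bg]
            if not values:
                out[image_id] = 0.0 if method == "background_sum" else table.global_mean
            else:
                out[image_id] = float(
                    np.sum(values) if method == "background_sum" else np.mean(values)
                )
    return out


def vectorize_tags(
    tags: Iterable[ObjectTag],
    vocabulary: Sequence[str] | None = None,
    allow_unknown: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Presence (0/1) and count vectors per image over a fixed class vocabulary.

    Returns ``(presence, counts)`` DataFrames indexed by image id with one
    column per vocabulary entry.  Unknown classes raise unless
    ``allow_unknown`` maps them to an OTHER bucket column.
    """
    if vocabulary is None:
        from .simulate import VOC_CLASSES

        vocabulary = VOC_CLASSES
    columns = list(vocabulary) + (["OTHER"] if allow_unknown else [])
    col_index = {c: i for i, c in enumerate(columns)}
    grouped = _group_by_image(tags)
    counts = np.zeros((len(grouped), len(columns)), dtype=np.int64)
    for row, (image_id, image_tags) in enumerate(grouped.items()):
        for tag in image_tags:
            if tag.class_name in col_index:
                counts[row, col_index[tag.class_name]] += 1
            elif allow_unknown:
                counts[row, col_index["OTHER"]] += 1
            else:
                raise ValidationError(
                    f"class {tag.class_name!r} not in vocabulary; pass allow_unknown=True"
                )
    index = pd.Index(list(grouped), name="image_id")
    counts_df = pd.DataFrame(counts, index=index, columns=columns)
    presence_df = (counts_df > 0).astype(np.int64)
    return presence_df, counts_df


def read_voc_xml(path: str | Path) -> list[ObjectTag]:
    """Parse one VOC-style annotation XML file into ObjectTag records.

    VOC boxes are 1-based inclusive; they are converted to 0-based half-open.
    """
    path = Path(path)
    root = ET.parse(path).getroot()
    image_id = root.findtext("filename") or path.stem
    image_id = Path(image_id).stem
    tags = []
    for obj in root.findall("object"):
        name = obj.findtext("name")
        box = obj.find("bndbox")
        if name is None or box is None:
            raise ValidationError(f"{path}: object without name or bndbox")
        xmin = int(float(box.findtext("xmin"))) - 1
        ymin = int(float(box.findtext("ymin"))) - 1
        xmax = int(float(box.findtext("xmax")))
        ymax = int(float(box.findtext("ymax")))
        tags.append(ObjectTag(image_id=image_id, class_name=name, bbox=(xmin, ymin, xmax, ymax)))
    return tags


def read_tags_json(path: str | Path) -> list[ObjectTag]:
    """Read the JSON tag format: a list of {image_id, class, bbox} records."""
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    tags = []
    for i, rec in enumerate(data):
        try:
            tags.append(
                ObjectTag(
                    image_id=rec["image_id"],
                    class_name=rec["class"],
                    bbox=tuple(int(v) for v in rec["bbox"]),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"{path}: bad tag record #{i}: {exc}") from exc
    return tags


def write_tags_json(tags: Iterable[ObjectTag], path: str | Path) -> None:
    data = [
        {"image_id": t.image_id, "class": t.class_name, "bbox": list(t.bbox)} for t in tags
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=1)
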