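"""HDF5 study-bundle container and TSV table I/O.

A *study bundle* packages one cohort: the shared voxel geometry, every
participant's PSC tensor, the concept table, optional ratings, and (for
synthetic data) the generator's ground truth. Tables travel as TSV
(tab-separated, UTF-8, LF, header row) both on disk and embedded inside
the HDF5 container, so every number in a report is traceable to a
plain-text artifact.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .geometry import BrainGeometry
from .synth import ActivationDataset, GroundTruth, PlantedCluster, RatingsMatrix

FORMAT_VERSION = 1


@dataclass
class StudyBundle:
    geometry: BrainGeometry
    datasets: list[ActivationDataset]
    concept_table: pd.DataFrame
    ratings: RatingsMatrix | None = None
    ground_truth: GroundTruth | None = None


def _df_to_tsv(df: pd.DataFrame) -> str:
    return df.to_csv(sep="\t", index=False, lineterminator="\n")


def _tsv_to_df(text: str) -> pd.DataFrame:
    return pd.read_csv(_io.StringIO(text), sep="\t")


def write_bundle(bundle: StudyBundle, path) -> None:
    geom = bundle.geometry
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        g = f.create_group("geometry")
        g.create_dataset("grid_shape", data=np.asarray(geom.grid_shape))
        g.create_dataset("voxel_size_mm", data=np.asarray(geom.voxel_size_mm))
        g.create_dataset("origin_mm", data=np.asarray(geom.origin_mm))
        g.create_dataset("lobe_codes", data=geom.lobe_codes)
        g.attrs["lobe_names"] = list(geom.lobe_names)
        parts = f.create_group("participants")
        for ds in bundle.datasets:
            pg = parts.create_group(ds.participant_id)
            pg.create_dataset("psc", data=ds.psc)
            pg.attrs["group"] = ds.group
            pg.attrs["participant_index"] = ds.participant_index
        tables = f.create_group("tables")
        tables.create_dataset("concepts", data=_df_to_tsv(bundle.concept_table))
        if bundle.ratings is not None:
            rt = bundle.ratings
            df = pd.DataFrame(rt.values, columns=list(rt.dimension_names))
            df.insert(0, "concept", rt.concept_labels)
            d = tables.create_dataset("ratings", data=_df_to_tsv(df))
            d.attrs["rater_count"] = rt.rater_count
        if bundle.ground_truth is not None:
            gt = bundle.ground_truth
            tg = f.create_group("ground_truth")
            tg.create_dataset("concept_scores", data=gt.concept_scores)
            tg.attrs["dimension_names"] = list(gt.dimension_names)
            tg.attrs["concept_labels"] = list(gt.concept_labels)
            for name, lm in gt.loading_maps.items():
                tg.create_dataset(f"loading_map_{name}", data=lm)
            spec = {
                grp: [
                    {"dimension": c.dimension, "lobe": c.lobe,
                     "seed_voxel": c.seed_voxel, "voxels": list(c.voxels)}
                    for c in clusters
                ]
                for grp, clusters in gt.cluster_specs.items()
            }
            tg.create_dataset("cluster_specs", data=json.dumps(spec, sort_keys=True))
            tg.attrs["noise_sd"] = gt.noise_sd
            tg.attrs["participant_sd"] = gt.participant_sd
            tg.attrs["group_effect"] = gt.group_effect
            tg.attrs["seed"] = gt.seed


def read_bundle(path) -> StudyBundle:
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise OSError(f"cannot open study bundle {path!r}: {exc}") from exc
    with f:
        version = f.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise ValueError(
                f"bundle format version mismatch: got {version!r}, "
                f"expected {FORMAT_VERSION}"
            )
        for required in ("geometry", "participants", "tables"):
            if required not in f:
                raise ValueError(f"bundle is missing mandatory group {required!r}")
        g = f["geometry"]
        geom = BrainGeometry(
            grid_shape=tuple(int(x) for x in g["grid_shape"][()]),
            voxel_size_mm=tuple(float(x) for x in g["voxel_size_mm"][()]),
            lobe_codes=g["lobe_codes"][()],
            origin_mm=tuple(float(x) for x in g["origin_mm"][()]),
            lobe_names=tuple(str(x) for x in g.attrs["lobe_names"]),
        )
        concept_table = _tsv_to_df(_as_str(f["tables/concepts"][()]))
        labels = concept_table["label"].tolist()
        datasets = []
        for pid in sorted(f["participants"]):
            pg = f["participants"][pid]
            datasets.append(
                ActivationDataset(
                    participant_id=pid,
                    participant_index=int(pg.attrs["participant_index"]),
                    group=str(pg.attrs["group"]),
                    psc=pg["psc"][()],
                    concept_labels=labels,
                    geometry=geom,
                )
            )
        datasets.sort(key=lambda d: d.participant_index)
        ratings = None
        if "ratings" in f["tables"]:
            d = f["tables/ratings"]
            df = _tsv_to_df(_as_str(d[()]))
            ratings = RatingsMatrix(
                values=df.drop(columns="concept").to_numpy(float),
                dimension_names=tuple(c for c in df.columns if c != "concept"),
                concept_labels=df["concept"].tolist(),
                rater_count=int(d.attrs["rater_count"]),
            )
        ground_truth = None
        if "ground_truth" in f:
            tg = f["ground_truth"]
            spec = json.loads(_as_str(tg["cluster_specs"][()]))
            cluster_specs = {
                grp: [
                    PlantedCluster(
                        dimension=c["dimension"], lobe=c["lobe"],
                        seed_voxel=int(c["seed_voxel"]),
                        voxels=tuple(int(v) for v in c["voxels"]),
                    )
                    for c in clusters
                ]
                for grp, clusters in spec.items()
            }
            loading_maps = {
                key[len("loading_map_"):]: tg[key][()]
                for key in tg
                if key.startswith("loading_map_")
            }
            ground_truth = GroundTruth(
                geometry=geom,
                concept_labels=[str(x) for x in tg.attrs["concept_labels"]],
                dimension_names=tuple(str(x) for x in tg.attrs["dimension_names"]),
                concept_scores=tg["concept_scores"][()],
                loading_maps=loading_maps,
                cluster_specs=cluster_specs,
                noise_sd=float(tg.attrs["noise_sd"]),
                participant_sd=float(tg.attrs["participant_sd"]),
                group_effect=float(tg.attrs["group_effect"]),
                seed=int(tg.attrs["seed"]),
            )
        return StudyBundle(
            geometry=geom,
            datasets=datasets,
            concept_table=concept_table,
            ratings=ratings,
            ground_truth=ground_truth,
        )


def _as_str(x) -> str:
    return x.decode() if isinstance(x, bytes) else str(x)


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def read_ratings_tsv(path) -> RatingsMatrix:
    """Read a ratings table (header row of dimension names, one concept per row).

    Values are validated to the 1-7 scale (the offending cell is named);
    duplicate concepts are rejected; concept order is preserved.
    """
    df = pd.read_csv(path, sep="\t")
    if "concept" not in df.columns:
        raise ValueError("ratings TSV must have a 'concept' column")
    concepts = df["concept"].tolist()
    dupes = df["concept"][df["concept"].duplicated()]
    if not dupes.empty:
        raise ValueError(f"duplicate concept {dupes.iloc[0]!r} in ratings table")
    dims = [c for c in df.columns if c != "concept"]
    values = df[dims].to_numpy(float)
    bad = np.argwhere((values < 1) | (values > 7) | ~np.isfinite(values))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"rating out of range [1, 7] at concept {concepts[r]!r}, "
            f"dimension {dims[c]!r}: {values[r, c]}"
        )
    return RatingsMatrix(
        values=values,
        dimension_names=tuple(dims),
        concept_labels=concepts,
        rater_count=0,
    )


def write_ratings_tsv(ratings: RatingsMatrix, path) -> None:
    df = pd.DataFrame(ratings.values, columns=list(ratings.dimension_names))
    df.insert(0, "concept", ratings.concept_labels)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_stability_tsv(stability, geometry: BrainGeometry, path) -> None:
    scores = stability.scores if hasattr(stability, "scores") else np.asarray(stability)
    ijk = geometry.index_to_grid(np.arange(geometry.n_voxels))
    df = pd.DataFrame(
        {
            "voxel": np.arange(geometry.n_voxels),
            "x": ijk[:, 0], "y": ijk[:, 1], "z": ijk[:, 2],
            "lobe": [geometry.lobe_of(v) for v in range(geometry.n_voxels)],
            "score": scores,
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_factor_scores_tsv(scores: np.ndarray, concept_labels: list[str], path) -> None:
    df = pd.DataFrame(
        scores, columns=[f"factor_{i}" for i in range(scores.shape[1])]
    )
    df.insert(0, "concept", concept_labels)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_clusters_tsv(cluster_map, path) -> None:
    rows = [
        {
            "factor": c.factor,
            "size": c.size,
            "centroid_x_mm": c.centroid_mm[0],
            "centroid_y_mm": c.centroid_mm[1],
            "centroid_z_mm": c.centroid_mm[2],
        }
        for c in cluster_map.clusters
    ]
    pd.DataFrame(rows, columns=["factor", "size", "centroid_x_mm",
                                "centroid_y_mm", "centroid_z_mm"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def write_cv_report_tsv(result, path, fold_column: str = "fold") -> None:
    n_folds = max(len(result.folds), 1)
    per_fold = np.array_split(result.per_item, n_folds)
    rows = []
    for f, chunk in enumerate(per_fold):
        for i, v in enumerate(chunk):
            rows.append({fold_column: f, "item": i, "normalized_rank_accuracy": v})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
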