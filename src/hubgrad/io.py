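"""Plain-text readers and writers for every artifact the pipeline touches.

Matrices are dense TSV with no header; tables are TSV with a header row;
gradient sets pair a TSV of scores with a JSON metadata sidecar.  Floats
are written with a fixed repr so identical inputs produce byte-identical
files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .embedding import GradientSet

FLOAT_FMT = "%.12g"


def write_matrix(path, matrix) -> None:
    np.savetxt(path, np.asarray(matrix, float), fmt=FLOAT_FMT, delimiter="\t")


def read_matrix(path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", ndmin=2)


def write_table(path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.12g")


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_parcellation(path, parcellation) -> None:
    df = pd.DataFrame(
        {
            "node_id": parcellation.node_id,
            "x": parcellation.centroids[:, 0],
            "y": parcellation.centroids[:, 1],
            "z": parcellation.centroids[:, 2],
            "hemisphere": parcellation.hemisphere,
            "network": parcellation.network_label,
            "braak": parcellation.braak_label,
        }
    )
    write_table(path, df)


def read_parcellation_table(path) -> pd.DataFrame:
    return read_table(path)


def write_gradient_set(prefix, gradients: GradientSet, extra_meta: dict | None = None) -> None:
    """Write scores to ``<prefix>.tsv`` and metadata to ``<prefix>.json``."""
    prefix = Path(prefix)
    n, k = gradients.scores.shape
    df = pd.DataFrame(
        gradients.scores, columns=[f"G{i + 1}" for i in range(k)]
    )
    df.insert(0, "node_id", np.arange(n))
    write_table(prefix.with_suffix(".tsv"), df)
    meta = {
        "kernel": gradients.kernel,
        "alpha": None if np.isnan(gradients.alpha) else gradients.alpha,
        "diffusion_time": gradients.diffusion_time,
        "template_id": gradients.template_id,
        "eigenvalues": gradients.eigenvalues.tolist(),
        "explained_info": gradients.explained_info.tolist(),
    }
    if extra_meta:
        meta.update(extra_meta)
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_gradient_set(prefix) -> GradientSet:
    prefix = Path(prefix)
    df = read_table(prefix.with_suffix(".tsv"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    scores = df[[c for c in df.columns if c.startswith("G")]].to_numpy(float)
    return GradientSet(
        scores=scores,
        eigenvalues=np.asarray(meta["eigenvalues"], float),
        kernel=meta["kernel"],
        alpha=meta["alpha"] if meta["alpha"] is not None else np.nan,
        diffusion_time=meta["diffusion_time"],
        template_id=meta["template_id"],
        explained_info=np.asarray(meta["explained_info"], float),
    )


def write_suvr_table(path, maps: dict, tracer: str, visit: str) -> None:
    """``maps``: subject_id -> N-vector."""
    rows = []
    for sid, values in maps.items():
        row = {"subject_id": sid, "tracer": tracer, "visit": visit}
        row.update({f"v{i}": v for i, v in enumerate(np.asarray(values, float))})
        rows.append(row)
    write_table(path, pd.DataFrame(rows))


def read_suvr_table(path) -> dict:
    df = read_table(path)
    vcols = [c for c in df.columns if c.startswith("v") and c[1:].isdigit()]
    vcols.sort(key=lambda c: int(c[1:]))
    return {r["subject_id"]: r[vcols].to_numpy(float) for _, r in df.iterrows()}


def write_statmap(prefix, statmap) -> None:
    prefix = Path(prefix)
    df = pd.DataFrame(
        {
            "node_id": np.arange(statmap.t.size),
            "t": statmap.t,
            "p": statmap.p,
            "significant": statmap.significant.astype(int),
        }
    )
    write_table(prefix.with_suffix(".tsv"), df)
    meta = {
        "contrast": statmap.contrast_label,
        "covariates": list(statmap.covariates_used),
        **{k: v for k, v in statmap.meta.items() if isinstance(v, (int, float, str, list))},
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def write_subjects(path, subjects) -> None:
    rows = [
        {
            "subject_id": s.subject_id,
            "group": s.group,
            "age": s.age,
            "sex": s.sex,
            "apoe4": s.apoe4,
            "education": s.education,
            "visit_times": ",".join(str(v) for v in s.visit_times),
        }
        for s in subjects
    ]
    write_table(path, pd.DataFrame(rows))


def read_subjects(path) -> pd.DataFrame:
    return read_table(path)
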