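"""Delimited-text I/O for genotype and phenotype tables.

Dialect: CSV/TSV with a header row of marker ids (or trait names), first
column holding the sample id, and "NA" for missing genotypes. A sidecar JSON
manifest can record the coding, simulation seed, QTL ground truth and split
indices so a simulated dataset round-trips exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simdata import MISSING, DataSplit, GenotypeMatrix, QTLTruth, TraitData

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_traits",
    "write_traits",
    "write_manifest",
    "read_manifest",
    "write_report",
]


class ParseError(ValueError):
    pass


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def write_genotypes(G: GenotypeMatrix, path):
    vals = G.values.astype(object)
    vals[G.values == MISSING] = "NA"
    df = pd.DataFrame(vals, index=G.sample_ids, columns=G.marker_ids)
    df.to_csv(path, sep=_sep(path), index_label="sample_id")


def read_genotypes(path, coding: str | None = None) -> GenotypeMatrix:
    """Parse a genotype table; codes are validated against the coding.

    If `coding` is None it is inferred: matrices whose maximum observed code
    is 1 are treated as dominant 0/1, otherwise additive 0/1/2.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"genotype file not found: {path}")
    df = pd.read_csv(path, sep=_sep(path), index_col=0, na_values=["NA"],
                     keep_default_na=False)
    vals = df.to_numpy()
    out = np.full(vals.shape, MISSING, dtype=np.int16)
    obs_max = 0
    for i in range(vals.shape[0]):
        for j in range(vals.shape[1]):
            v = vals[i, j]
            if isinstance(v, float) and np.isnan(v):
                continue
            try:
                iv = int(v)
                if iv != float(v):
                    raise ValueError
            except (TypeError, ValueError):
                raise ParseError(
                    f"non-integer genotype code {v!r} at line {i + 2}, "
                    f"marker {df.columns[j]!r}"
                ) from None
            out[i, j] = iv
            obs_max = max(obs_max, iv)
    if coding is None:
        coding = "dominant_01" if obs_max <= 1 else "additive_012"
    limit = 1 if coding == "dominant_01" else 2
    bad = np.argwhere((out != MISSING) & ((out < 0) | (out > limit)))
    if bad.size:
        i, j = bad[0]
        raise ParseError(
            f"genotype code {out[i, j]} out of range for {coding} at line "
            f"{i + 2}, marker {df.columns[j]!r}"
        )
    return GenotypeMatrix(values=out, sample_ids=[str(s) for s in df.index],
                          marker_ids=[str(c) for c in df.columns], coding=coding)


def write_traits(T: TraitData, path, sample_ids=None):
    n = len(T.values)
    idx = sample_ids if sample_ids is not None else [f"S{i}" for i in range(n)]
    if T.mode == "regression":
        df = pd.DataFrame(T.values, index=idx, columns=T.trait_names)
    else:
        df = pd.DataFrame({"class": T.values}, index=idx)
    df.to_csv(path, sep=_sep(path), index_label="sample_id")


def read_traits(path) -> TraitData:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"phenotype file not found: {path}")
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if list(df.columns) == ["class"]:
        labels = df["class"].to_numpy()
        if not np.all(labels == labels.astype(int)):
            raise ParseError("class labels must be integers")
        labels = labels.astype(int)
        return TraitData(mode="classification", values=labels,
                         n_classes=int(labels.max()) + 1)
    vals = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        i = int(np.argwhere(~np.isfinite(vals))[0, 0])
        raise ParseError(f"non-finite trait value at line {i + 2}")
    return TraitData(mode="regression", values=vals,
                     trait_names=[str(c) for c in df.columns])


def write_manifest(path, *, coding: str, seed: int, truth: QTLTruth | None = None,
                   split: DataSplit | None = None, extra: dict | None = None):
    doc = {"coding": coding, "seed": int(seed)}
    if truth is not None:
        doc["qtl_truth"] = {
            "causal_indices": [list(map(int, idx)) for idx in truth.causal_indices],
            "effects_nonzero": {
                f"{i},{t}": float(truth.effects[i, t])
                for i, t in zip(*np.nonzero(truth.effects))
            },
            "effects_shape": list(truth.effects.shape),
            "epistatic_terms": [
                [int(i), int(j), int(t), float(c)] for i, j, t, c in truth.epistatic_terms
            ],
        }
    if split is not None:
        doc["split"] = {
            "train_idx": split.train_idx.tolist(),
            "val_idx": split.val_idx.tolist(),
            "test_idx": split.test_idx.tolist(),
            "fractions": list(split.fractions),
        }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=1))


def read_manifest(path) -> dict:
    doc = json.loads(Path(path).read_text())
    if "split" in doc:
        s = doc["split"]
        doc["split"] = DataSplit(
            train_idx=np.array(s["train_idx"]),
            val_idx=np.array(s["val_idx"]),
            test_idx=np.array(s["test_idx"]),
            fractions=tuple(s["fractions"]),
        )
    if "qtl_truth" in doc:
        q = doc["qtl_truth"]
        effects = np.zeros(q["effects_shape"])
        for key, val in q["effects_nonzero"].items():
            i, t = map(int, key.split(","))
            effects[i, t] = val
        doc["qtl_truth"] = QTLTruth(
            causal_indices=[np.array(ix, dtype=int) for ix in q["causal_indices"]],
            effects=effects,
            epistatic_terms=[tuple(e) for e in q["epistatic_terms"]],
        )
    return doc


def write_report(report: dict, path):
    Path(path).write_text(json.dumps(report, indent=1, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
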