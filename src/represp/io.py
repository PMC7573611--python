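"""Delimited-text readers and writers for expression and response tables.

Expression tables are long format by default (columns patient, gene, time,
value) with an explicit NA token for missing entries — readers reject rather
than coerce: negative values, duplicate (patient, gene, time) triples and
unknown tokens are errors, never silently fixed. Time labels are ordered
categoricals: they are sorted numerically when possible, and an explicit
``time_order`` is required otherwise (time arithmetic is never performed;
only chronology matters to the model).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .feedback import CLASSIFICATION, ResponseMatrix
from .tensor_model import GexTensor

__all__ = [
    "read_expression",
    "write_expression",
    "read_responses",
    "write_responses",
]

NA_TOKEN = "NA"


def _sep(path, delimiter):
    if delimiter is not None:
        return delimiter
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def _order_times(labels, time_order):
    labels = list(labels)
    if time_order is not None:
        missing = set(labels) - set(time_order)
        if missing:
            raise ValueError(f"time labels {sorted(missing)} absent from time_order")
        return [t for t in time_order if t in labels]
    try:
        return sorted(labels, key=float)
    except (TypeError, ValueError):
        pass
    # shared non-numeric prefix with numeric tail, e.g. t0, t1, ..., month3
    import re

    parts = [re.fullmatch(r"(\D*)(\d+(?:\.\d+)?)", str(l)) for l in labels]
    if all(parts) and len({m.group(1) for m in parts}) == 1:
        return sorted(labels, key=lambda l: float(re.fullmatch(r"(\D*)(\d+(?:\.\d+)?)", str(l)).group(2)))
    raise ValueError(
        "time labels are not numerically ordered strings; pass an explicit time_order"
    )


def read_expression(path, layout: str = "long", na_token: str = NA_TOKEN,
                    time_order=None, delimiter=None) -> GexTensor:
    """Read an expression table into a patient x gene x time tensor.

    ``layout="long"`` expects columns patient, gene, time, value;
    ``layout="wide"`` expects columns patient, gene followed by one column
    per time label.
    """
    sep = _sep(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if layout == "wide":
        need = {"patient", "gene"}
        if not need.issubset(df.columns):
            raise ValueError(f"wide layout requires columns {sorted(need)}")
        time_cols = [c for c in df.columns if c not in need]
        df = df.melt(id_vars=["patient", "gene"], value_vars=time_cols,
                     var_name="time", value_name="value")
    elif layout != "long":
        raise ValueError(f"unknown layout {layout!r}")
    need = {"patient", "gene", "time", "value"}
    if not need.issubset(df.columns):
        raise ValueError(f"long layout requires columns {sorted(need)}")

    dup = df.duplicated(subset=["patient", "gene", "time"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate (patient, gene, time) triple: "
            f"({row['patient']}, {row['gene']}, {row['time']})"
        )
    is_na = df["value"] == na_token
    bad = pd.to_numeric(df["value"].where(~is_na), errors="coerce").isna() & ~is_na
    if bad.any():
        row = df[bad].iloc[0]
        raise ValueError(
            f"unparseable value {row['value']!r} at ({row['patient']}, "
            f"{row['gene']}, {row['time']}); unknown NA token?"
        )
    # .astype(float) round-trips repr() output exactly; pd.to_numeric does not
    vals = df["value"].where(~is_na).astype(float)
    neg = vals < 0
    if neg.any():
        row = df[neg.fillna(False)].iloc[0]
        raise ValueError(
            f"negative expression value {row['value']} at ({row['patient']}, "
            f"{row['gene']}, {row['time']})"
        )

    patients = list(dict.fromkeys(df["patient"]))
    genes = list(dict.fromkeys(df["gene"]))
    times = _order_times(dict.fromkeys(df["time"]), time_order)
    I, J, K = len(patients), len(genes), len(times)
    values = np.full((I, J, K), np.nan)
    mask = np.zeros((I, J, K), dtype=bool)
    pi = {p: i for i, p in enumerate(patients)}
    gi = {g: j for j, g in enumerate(genes)}
    ti = {t: k for k, t in enumerate(times)}
    ii = df["patient"].map(pi).to_numpy()
    jj = df["gene"].map(gi).to_numpy()
    kk = df["time"].map(ti).to_numpy()
    obs = ~is_na.to_numpy()
    values[ii[obs], jj[obs], kk[obs]] = vals.to_numpy()[obs]
    mask[ii[obs], jj[obs], kk[obs]] = True
    return GexTensor(values, mask, patients, genes, times)


def write_expression(tensor: GexTensor, path, na_token: str = NA_TOKEN, delimiter=None):
    """Write a tensor as a long-format table; missing entries get the NA token."""
    sep = _sep(path, delimiter)
    rows = []
    I, J, K = tensor.shape
    for i in range(I):
        for j in range(J):
            for k in range(K):
                v = (repr(float(tensor.values[i, j, k])) if tensor.mask[i, j, k]
                     else na_token)
                rows.append((tensor.patient_ids[i], tensor.gene_names[j],
                             tensor.time_labels[k], v))
    pd.DataFrame(rows, columns=["patient", "gene", "time", "value"]).to_csv(
        path, sep=sep, index=False)


def read_responses(path, task: str, tensor: GexTensor = None, label_map=None,
                   na_token: str = NA_TOKEN, delimiter=None) -> ResponseMatrix:
    """Read a patient x time response table aligned to a tensor's axes.

    ``label_map`` maps classification tokens to +1/-1 (e.g.
    ``{"good": 1, "poor": -1}``); numeric +1/-1 is accepted without a map.
    Patients or time labels absent from the tensor are rejected.
    """
    sep = _sep(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    need = {"patient", "time", "response"}
    if not need.issubset(df.columns):
        raise ValueError(f"response table requires columns {sorted(need)}")
    if tensor is not None:
        patients, times = list(tensor.patient_ids), list(tensor.time_labels)
    else:
        patients = list(dict.fromkeys(df["patient"]))
        times = _order_times(dict.fromkeys(df["time"]), None)
    pi = {p: i for i, p in enumerate(patients)}
    ti = {t: k for k, t in enumerate(times)}
    I, K = len(patients), len(times)
    values = np.full((I, K), np.nan)
    for _, row in df.iterrows():
        if row["patient"] not in pi:
            raise ValueError(f"response for unknown patient {row['patient']!r}")
        if row["time"] not in ti:
            raise ValueError(f"response at unknown time label {row['time']!r}")
        tok = row["response"]
        if tok == na_token:
            continue
        if task == CLASSIFICATION:
            if label_map is not None and tok in label_map:
                y = float(label_map[tok])
            else:
                try:
                    y = float(tok)
                except ValueError:
                    raise ValueError(f"label {tok!r} outside the declared label pair")
            if y not in (-1.0, 1.0):
                raise ValueError(f"label {tok!r} outside the declared label pair")
        else:
            y = float(tok)
        values[pi[row["patient"]], ti[row["time"]]] = y
    return ResponseMatrix(values, np.isfinite(values), task, patients, times)


def write_responses(responses: ResponseMatrix, path, na_token: str = NA_TOKEN,
                    delimiter=None):
    sep = _sep(path, delimiter)
    rows = []
    I, K = responses.shape
    pids = responses.patient_ids or [f"P{i}" for i in range(I)]
    tls = responses.time_labels or [f"t{k}" for k in range(K)]
    for i in range(I):
        for k in range(K):
            v = repr(float(responses.values[i, k])) if responses.mask[i, k] else na_token
            rows.append((pids[i], tls[k], v))
    pd.DataFrame(rows, columns=["patient", "time", "response"]).to_csv(
        path, sep=sep, index=False)
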