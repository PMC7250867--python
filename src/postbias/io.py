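"""Serialization of the pipeline's artifacts.

Trial tables travel as CSV with a fixed column set; epochs, fit bundles,
temporal-generalization matrices and sensor maps travel as HDF5 with axis
metadata.  Every writer has a matching reader and write-then-read returns
an equal artifact.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import h5py
import numpy as np
import pandas as pd

from .ddm import FitConfig, FitResult, ModelSpec
from .neural import EpochSet, SensorContributionMap, TGMatrix

TRIAL_COLUMNS = [
    "subject_id", "pe_condition", "post_strength", "direction",
    "initial_choice", "initial_correct", "initial_confidence", "initial_rt",
    "final_choice", "final_correct", "final_confidence", "final_rt",
    "change_of_mind",
]


class FormatError(ValueError):
    """Raised when a container does not match the documented layout."""


def write_trials(table: pd.DataFrame, path) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"trial table missing columns: {missing}")
    if table[TRIAL_COLUMNS].isna().any().any():
        raise FormatError("trial table contains missing values")
    cols = TRIAL_COLUMNS + [c for c in table.columns if c not in TRIAL_COLUMNS]
    table[cols].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"not a trial table (missing {missing})")
    if table[TRIAL_COLUMNS].isna().any().any():
        raise FormatError("trial table contains missing values")
    return table


def write_epochs(epochs: EpochSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=epochs.data, compression="gzip", compression_opts=1)
        f.create_dataset("times_ms", data=epochs.times)
        f.create_dataset("channels", data=np.array(epochs.channels, dtype="S"))
        f.create_dataset("trial_index", data=np.arange(epochs.n_trials))
        f.attrs["sampling_rate_hz"] = epochs.sampling_rate
        f.attrs["alignment"] = epochs.alignment
        g = f.create_group("labels")
        g.attrs["columns"] = np.array(list(epochs.labels.columns), dtype="S")
        for col in epochs.labels.columns:
            vals = epochs.labels[col].to_numpy()
            if vals.dtype.kind in "OUS":
                vals = vals.astype("S")
            g.create_dataset(col, data=vals)


def read_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        for key in ("epochs", "times_ms", "channels"):
            if key not in f:
                raise FormatError(f"epoch container missing dataset {key!r}")
        data = f["epochs"][()]
        times = f["times_ms"][()]
        channels = [c.decode() for c in f["channels"][()]]
        labels = {}
        order = [c.decode() for c in f["labels"].attrs["columns"]]
        for col in order:
            vals = f["labels"][col][()]
            if vals.dtype.kind == "S":
                vals = np.array([v.decode() for v in vals])
            labels[col] = vals
        return EpochSet(
            data=data,
            sampling_rate=float(f.attrs["sampling_rate_hz"]),
            times=times,
            labels=pd.DataFrame(labels),
            channels=channels,
            alignment=str(f.attrs["alignment"]),
        )


def write_fit(result: FitResult, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("draws")
        for name, arr in result.draws.items():
            g.create_dataset(name, data=arr)
        f.create_dataset("deviance", data=result.deviance)
        rh = f.create_group("rhat")
        for name, val in result.rhat.items():
            rh.attrs[name] = val
        f.attrs["dic"] = result.dic_ if result.dic_ is not None else np.nan
        f.attrs["converged"] = bool(result.converged)
        f.attrs["n_retained"] = result.n_retained
        f.attrs["model_spec"] = json.dumps(
            {"model_id": result.model.model_id,
             "z_terms": list(result.model.z_terms),
             "v_terms": list(result.model.v_terms),
             "a_terms": list(result.model.a_terms)}
        )
        f.attrs["fit_config"] = json.dumps(asdict(result.config))
        f.attrs["acceptance"] = json.dumps(result.acceptance)


def read_fit(path) -> FitResult:
    with h5py.File(path, "r") as f:
        if "draws" not in f or "deviance" not in f:
            raise FormatError("not a fit bundle")
        draws = {name: ds[()] for name, ds in f["draws"].items()}
        spec_d = json.loads(f.attrs["model_spec"])
        spec = ModelSpec(
            model_id=spec_d["model_id"],
            z_terms=tuple(spec_d["z_terms"]),
            v_terms=tuple(spec_d["v_terms"]),
            a_terms=tuple(spec_d["a_terms"]),
        )
        config = FitConfig(**json.loads(f.attrs["fit_config"]))
        dic_val = float(f.attrs["dic"])
        return FitResult(
            draws=draws,
            deviance=f["deviance"][()],
            rhat=dict(f["rhat"].attrs),
            converged=bool(f.attrs["converged"]),
            n_retained=int(f.attrs["n_retained"]),
            model=spec,
            config=config,
            dic_=None if np.isnan(dic_val) else dic_val,
            acceptance=json.loads(f.attrs["acceptance"]),
        )


def write_tg(tg: TGMatrix, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("overall", data=tg.overall)
        g = f.create_group("by_cell")
        for name, mat in tg.by_cell.items():
            g.create_dataset(name, data=mat)
        f.create_dataset("train_times_ms", data=tg.train_times_ms)
        f.create_dataset("test_times_ms", data=tg.test_times_ms)
        f.attrs["folds"] = tg.folds
        f.attrs["reps"] = tg.reps


def read_tg(path) -> TGMatrix:
    with h5py.File(path, "r") as f:
        if "overall" not in f:
            raise FormatError("not a temporal-generalization container")
        return TGMatrix(
            overall=f["overall"][()],
            by_cell={k: ds[()] for k, ds in f["by_cell"].items()},
            train_times_ms=f["train_times_ms"][()],
            test_times_ms=f["test_times_ms"][()],
            folds=int(f.attrs["folds"]),
            reps=int(f.attrs["reps"]),
        )


def write_contributions(cmap: SensorContributionMap, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("contribution", data=cmap.contribution)
        f.create_dataset("counts", data=cmap.counts)
        f.attrs["subset_size"] = cmap.subset_size
        f.attrs["reps"] = cmap.reps


def read_contributions(path) -> SensorContributionMap:
    with h5py.File(path, "r") as f:
        if "contribution" not in f:
            raise FormatError("not a sensor-contribution container")
        return SensorContributionMap(
            contribution=f["contribution"][()],
            counts=f["counts"][()],
            subset_size=int(f.attrs["subset_size"]),
            reps=int(f.attrs["reps"]),
        )


def roundtrip(artifact, path):
    """Write an artifact to ``path`` and read it back (dispatch on type)."""
    if isinstance(artifact, pd.DataFrame):
        write_trials(artifact, path)
        return read_trials(path)
    if isinstance(artifact, EpochSet):
        write_epochs(artifact, path)
        return read_epochs(path)
    if isinstance(artifact, FitResult):
        write_fit(artifact, path)
        return read_fit(path)
    if isinstance(artifact, TGMatrix):
        write_tg(artifact, path)
        return read_tg(path)
    if isinstance(artifact, SensorContributionMap):
        write_contributions(artifact, path)
        return read_contributions(path)
    raise TypeError(f"no serializer for {type(artifact).__name__}")
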