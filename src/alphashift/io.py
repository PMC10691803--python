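"""On-disk layout for recordings, events and montages.

One recording = a flat binary array container (``<name>.npy``, sensors x
samples, float64 microvolts) + a JSON sidecar (``<name>.json`` with fs,
sensor labels, reference) + a tab-separated events file
(``<name>_events.tsv`` with columns ``onset_s`` and ``code``).  Montages
are tab-separated ``label x y z``.  Users with vendor-format EEG can adapt
any reader by constructing :class:`~alphashift.simulate.Recording` directly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Recording

__all__ = ["save_recording", "load_recording", "save_events", "load_events",
           "save_cohort", "DiskCohort"]


def save_events(events, fs: float, path) -> None:
    """Write events as a two-column TSV (onset_s, code).

    ``events`` holds ``(onset_sample, code)`` pairs as stored on a
    :class:`Recording`; onsets are converted to seconds.
    """
    df = pd.DataFrame(
        {"onset_s": [onset / fs for onset, _ in events],
         "code": [code for _, code in events]})
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def load_events(path, fs: float):
    df = pd.read_csv(path, sep="\t")
    return [(int(round(row.onset_s * fs)), str(row.code))
            for row in df.itertuples()]


def save_recording(rec: Recording, directory, name: str) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.save(d / f"{name}.npy", rec.data)
    meta = {"fs": rec.fs, "sensor_labels": rec.sensor_labels,
            "reference_tag": rec.reference_tag}
    (d / f"{name}.json").write_text(json.dumps(meta, indent=1))
    save_events(rec.events, rec.fs, d / f"{name}_events.tsv")


def load_recording(directory, name: str) -> Recording:
    d = Path(directory)
    data = np.load(d / f"{name}.npy")
    meta = json.loads((d / f"{name}.json").read_text())
    events_path = d / f"{name}_events.tsv"
    events = load_events(events_path, meta["fs"]) if events_path.exists() else []
    return Recording(data, meta["fs"], meta["sensor_labels"], events,
                     meta.get("reference_tag", "common_average"))


def save_cohort(cohort, directory) -> None:
    """Materialise a simulated cohort: recordings, cognition, ground truth."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for i in range(len(cohort)):
        rest, task, _ = cohort.subject(i)
        save_recording(rest, d, f"rest_{i:04d}")
        save_recording(task, d, f"task_{i:04d}")
    cohort.cognition.to_csv(d / "cognition.tsv", sep="\t", index=False)
    cohort.truth.to_csv(d / "truth.tsv", sep="\t", index=False)
    cohort.montage.to_frame().to_csv(d / "montage.tsv", sep="\t", index=False)
    (d / "meta.json").write_text(json.dumps(
        {"n_subjects": len(cohort), "master_seed": cohort.spec.master_seed}))


class DiskCohort:
    """A cohort previously written by :func:`save_cohort`.

    Mirrors the lazy-rendering interface of
    :class:`~alphashift.simulate.Cohort` so the group pipeline can run
    either from memory or from disk.
    """

    def __init__(self, directory):
        from .montage import load_montage
        self.directory = Path(directory)
        meta = json.loads((self.directory / "meta.json").read_text())
        self.n_subjects = int(meta["n_subjects"])
        self.cognition = pd.read_csv(self.directory / "cognition.tsv", sep="\t")
        truth_path = self.directory / "truth.tsv"
        self.truth = (pd.read_csv(truth_path, sep="\t")
                      if truth_path.exists() else None)
        self.montage = load_montage(self.directory / "montage.tsv")

    def __len__(self) -> int:
        return self.n_subjects

    def subject(self, i: int):
        rest = load_recording(self.directory, f"rest_{i:04d}")
        task = load_recording(self.directory, f"task_{i:04d}")
        return rest, task, None
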