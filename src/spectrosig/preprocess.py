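"""Epoch cleaning and re-referencing.

Order of operations is fixed: linear detrend of every epoch, amplitude
artifact rejection on the monopolar recordings (the rejection threshold is
defined per recorded contact), then bipolar derivation along each shaft.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import detrend as _scipy_detrend


def detrend_linear(epoch: np.ndarray) -> np.ndarray:
    """Remove the least-squares line from a voltage trace.

    A pure line maps to zeros; the residual has (numerically) zero mean and
    zero best-fit slope.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim not in (1, 2) or epoch.shape[-1] < 2:
        raise ValueError("need at least 2 samples")
    return _scipy_detrend(epoch, axis=-1, type="linear")


@dataclass
class ProbeEpochSet:
    """All epochs of one probe plus the rejection statistic sigma_images.

    ``sigma_images`` is the standard deviation of voltage over *all* this
    probe's epochs (whole -500..1000 ms window), computed once in a single
    pass; it is deliberately not re-estimated after exclusions.
    """

    probe_id: str
    epochs: np.ndarray  # (n_trials, n_samples)
    labels: np.ndarray | None = None
    sigma_images: float = field(init=False)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 2:
            raise ValueError("epochs must be a (n_trials, n_samples) array")
        self.sigma_images = float(self.epochs.std())


@dataclass
class RejectionReport:
    probe_id: str
    excluded: list[int]
    n_total: int
    sigma_images: float
    k: float
    usable: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                probe_id=self.probe_id,
                trial_index=self.excluded,
                reason=[f"max |v| >= {self.k:g} * sigma_images"] * len(self.excluded),
            )
        )


def reject_artifacts(
    probe_epochs: ProbeEpochSet, k: float = 10.0
) -> tuple[np.ndarray, RejectionReport]:
    """Drop epochs containing values >= k * sigma_images.

    Returns the boolean retain mask (aligned with trial order) and a report
    listing excluded trial indices.  If every epoch is excluded the probe is
    flagged unusable and downstream stages must skip it.  The operation is
    idempotent: retained epochs all satisfy the criterion against the
    original single-pass sigma_images.
    """
    sigma = probe_epochs.sigma_images
    peaks = np.abs(probe_epochs.epochs).max(axis=1)
    retain = peaks < k * sigma
    excluded = np.flatnonzero(~retain)
    usable = bool(retain.any())
    if not usable:
        warnings.warn(
            f"probe {probe_epochs.probe_id}: all epochs excluded at k={k}; "
            "probe flagged unusable"
        )
    report = RejectionReport(
        probe_id=probe_epochs.probe_id,
        excluded=excluded.tolist(),
        n_total=probe_epochs.epochs.shape[0],
        sigma_images=sigma,
        k=k,
        usable=usable,
    )
    return retain, report


@dataclass
class BipolarDerivation:
    """One derived probe: anode contact minus the next contact on the shaft."""

    probe_id: str
    anode_id: str
    cathode_id: str
    epochs: np.ndarray
    mni: tuple[float, float, float]


def bipolar_rereference(
    contacts: list[dict],
) -> list[BipolarDerivation]:
    """Derive bipolar signals along one shaft.

    ``contacts`` holds dicts with keys ``probe_id``, ``contact_index``,
    ``epochs`` (n_trials x n_samples, identical trial base across contacts)
    and ``mni``.  Contacts are sorted by ``contact_index``; derivation i is
    contact i minus contact i+1 (anode = lower index), so n contacts yield
    n-1 derived probes.  A derivation inherits the arithmetic midpoint of
    its contact pair's MNI coordinates.  Any component common to a contact
    pair cancels exactly.
    """
    ordered = sorted(contacts, key=lambda c: c["contact_index"])
    if len(ordered) < 2:
        warnings.warn("single-contact shaft: no bipolar derivations")
        return []
    out = []
    for a, b in zip(ordered[:-1], ordered[1:]):
        ea, eb = np.asarray(a["epochs"], float), np.asarray(b["epochs"], float)
        if ea.shape != eb.shape:
            raise ValueError("contacts on one shaft must share the trial/time base")
        mni = tuple(
            (np.asarray(a["mni"], float) + np.asarray(b["mni"], float)) / 2.0
        )
        out.append(
            BipolarDerivation(
                probe_id=f"{a['probe_id']}-{b['probe_id']}",
                anode_id=a["probe_id"],
                cathode_id=b["probe_id"],
                epochs=ea - eb,
                mni=mni,
            )
        )
    return out
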