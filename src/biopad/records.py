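"""Shared in-memory containers for the multimodal recording.

All pipelines operate on a :class:`MultiRateRecord`: two EEG channels at
400 Hz and the peripheral channels (EDA, SKT, two PPG wavelengths, tri-axial
acceleration) at 100 Hz, aligned on a common clock.  One wire frame carries
50 ms of signal, so a valid record always has ``len(eeg) == 4 * len(eda)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EEG_FS = 400.0
PERIPHERAL_FS = 100.0

#: EEG samples per frame (50 ms at 400 Hz) and peripheral samples per frame.
EEG_TICKS_PER_FRAME = 20
PERIPHERAL_TICKS_PER_FRAME = 5


@dataclass
class MultiRateRecord:
    """Aligned channel streams at their native sampling rates.

    Units are physical: EEG in microvolts at the electrode, EDA in
    microsiemens, SKT in degrees Celsius, PPG in ADC counts (arbitrary
    units), acceleration in g.
    """

    eeg: np.ndarray          # (n, 2) float, μV, 400 Hz
    eda: np.ndarray          # (m,) float, μS, 100 Hz
    skt: np.ndarray          # (m,) float, °C, 100 Hz
    ppg: np.ndarray          # (m, 2) float, counts (red, IR), 100 Hz
    accel: np.ndarray        # (m, 3) float, g, 100 Hz
    fs_eeg: float = EEG_FS
    fs_peripheral: float = PERIPHERAL_FS
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.eeg = np.atleast_2d(np.asarray(self.eeg, dtype=float))
        if self.eeg.shape[0] == 2 and self.eeg.shape[1] != 2:
            self.eeg = self.eeg.T
        self.eda = np.asarray(self.eda, dtype=float).ravel()
        self.skt = np.asarray(self.skt, dtype=float).ravel()
        self.ppg = np.asarray(self.ppg, dtype=float).reshape(-1, 2)
        self.accel = np.asarray(self.accel, dtype=float).reshape(-1, 3)
        m = len(self.eda)
        if not (len(self.skt) == len(self.ppg) == len(self.accel) == m):
            raise ValueError("peripheral channel lengths differ")

    @property
    def n_eeg(self) -> int:
        return self.eeg.shape[0]

    @property
    def n_peripheral(self) -> int:
        return len(self.eda)

    @property
    def duration_s(self) -> float:
        return self.n_peripheral / self.fs_peripheral

    def is_frame_aligned(self) -> bool:
        """True when the record divides into whole 50 ms frames."""
        return (
            self.n_eeg == 4 * self.n_peripheral
            and self.n_peripheral % PERIPHERAL_TICKS_PER_FRAME == 0
        )

    # ------------------------------------------------------------------ IO

    def eeg_frame(self) -> pd.DataFrame:
        t = np.arange(self.n_eeg) / self.fs_eeg
        return pd.DataFrame(
            {"time_s": t, "eeg1_uv": self.eeg[:, 0], "eeg2_uv": self.eeg[:, 1]}
        )

    def peripheral_frame(self) -> pd.DataFrame:
        t = np.arange(self.n_peripheral) / self.fs_peripheral
        return pd.DataFrame(
            {
                "time_s": t,
                "eda_us": self.eda,
                "skt_c": self.skt,
                "ppg_red": self.ppg[:, 0],
                "ppg_ir": self.ppg[:, 1],
                "accel_x_g": self.accel[:, 0],
                "accel_y_g": self.accel[:, 1],
                "accel_z_g": self.accel[:, 2],
            }
        )

    def to_csv(self, eeg_path, peripheral_path) -> None:
        """One CSV per sampling rate; first column is time in seconds."""
        self.eeg_frame().to_csv(eeg_path, index=False)
        self.peripheral_frame().to_csv(peripheral_path, index=False)

    @classmethod
    def from_csv(cls, eeg_path, peripheral_path) -> "MultiRateRecord":
        e = pd.read_csv(eeg_path)
        p = pd.read_csv(peripheral_path)
        return cls(
            eeg=e[["eeg1_uv", "eeg2_uv"]].to_numpy(),
            eda=p["eda_us"].to_numpy(),
            skt=p["skt_c"].to_numpy(),
            ppg=p[["ppg_red", "ppg_ir"]].to_numpy(),
            accel=p[["accel_x_g", "accel_y_g", "accel_z_g"]].to_numpy(),
        )

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["fs_eeg"] = self.fs_eeg
            f.attrs["fs_peripheral"] = self.fs_peripheral
            f.create_dataset("eeg_uv", data=self.eeg)
            f.create_dataset("eda_us", data=self.eda)
            f.create_dataset("skt_c", data=self.skt)
            f.create_dataset("ppg_counts", data=self.ppg)
            f.create_dataset("accel_g", data=self.accel)

    @classmethod
    def from_hdf5(cls, path) -> "MultiRateRecord":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                eeg=f["eeg_uv"][...],
                eda=f["eda_us"][...],
                skt=f["skt_c"][...],
                ppg=f["ppg_counts"][...],
                accel=f["accel_g"][...],
                fs_eeg=float(f.attrs["fs_eeg"]),
                fs_peripheral=float(f.attrs["fs_peripheral"]),
            )
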