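"""Model/results objects tying the pipeline together.

:class:`StrideLengthModel` is built from an IMU record plus stride-event
indices (and optional reference lengths) and estimates one length per
stride under one of three estimation modes:

* ``origin`` — no filtering: trapezoidal double integration of the raw
  measurement channel over each stride;
* ``ekf``    — wavelet + cubic-smoother preprocessing followed by the
  plain constant-Jacobian Kalman filter (gain regulation and sign-flip
  disabled);
* ``mekf``   — the same preprocessing followed by the modified filter
  with zero-crossing gain regulation and the sign-flip rule.

``fit()`` returns a :class:`StrideLengthResults` carrying the per-stride
estimates, the filtered state trajectories, error metrics against the
reference (when available) and a ``summary()`` table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .evalmetrics import MetricsReport, error_summary
from .gaitio import (
    ImuSequence,
    StrideEstimate,
    StrideEventIndex,
    StrideSegment,
    read_imu_csv,
    read_stride_events,
    segment_strides,
    write_estimates,
)
from .mekf import FilterConfig, FilterState, run_mekf, stride_length_from_states
from .preprocess import WaveletConfig, denoise_and_smooth

__all__ = ["StrideLengthModel", "StrideLengthResults", "MODES", "double_integrate_length"]

MODES = ("origin", "ekf", "mekf")


def double_integrate_length(samples: np.ndarray, dt: float) -> float:
    """|displacement| over a stride by cumulative trapezoidal double
    integration with zero initial velocity.

    A terminal zero-acceleration sample is appended so the integral spans
    the full stride period (the half-open segment excludes the next
    stride's first sample).
    """
    a = np.concatenate([np.asarray(samples, dtype=float), [0.0]])
    v = np.concatenate([[0.0], np.cumsum((a[1:] + a[:-1]) * 0.5 * dt)])
    p = np.trapezoid(v, dx=dt)
    return abs(float(p))


@dataclass
class StrideLengthResults:
    """Per-stride estimates and diagnostics produced by ``fit``."""

    model: "StrideLengthModel"
    estimates: list[StrideEstimate]
    segments: list[StrideSegment]
    filtered_states: list[list[FilterState]] | None
    metrics: MetricsReport | None

    @property
    def estimated_lengths(self) -> np.ndarray:
        return np.array([e.estimated_length for e in self.estimates])

    @property
    def reference_lengths(self) -> np.ndarray | None:
        refs = [e.reference_length for e in self.estimates]
        if any(r is None for r in refs):
            return None
        return np.array(refs, dtype=float)

    def filtered_segments(self) -> list[np.ndarray]:
        """Per-stride signal fed to downstream learning.

        For the filtered modes this is the posterior acceleration-state
        trajectory; for ``origin`` it is the raw segment.
        """
        if self.filtered_states is None:
            return [seg.samples for seg in self.segments]
        return [
            np.array([s.acceleration for s in states])
            for states in self.filtered_states
        ]

    def displacement_trajectories(self) -> list[np.ndarray]:
        if self.filtered_states is None:
            raise ValueError("origin mode has no filtered displacement states")
        return [
            np.array([s.displacement for s in states])
            for states in self.filtered_states
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stride_id": [e.stride_id for e in self.estimates],
                "estimated_length": [e.estimated_length for e in self.estimates],
                "reference_length": [e.reference_length for e in self.estimates],
                "error_percent": [e.error_percent for e in self.estimates],
            }
        )

    def save_estimates(self, path: str | Path) -> None:
        write_estimates(path, self.estimates)

    def summary(self) -> str:
        lines = [
            "Stride-length estimation results",
            "=" * 40,
            f"mode:            {self.model.mode}",
            f"measurement axis:{self.model.axis:>4s}",
            f"strides:         {len(self.estimates)}",
            f"mean est. length:{np.mean(self.estimated_lengths):9.4f} m",
        ]
        if self.metrics is not None:
            m = self.metrics
            lines += [
                "-" * 40,
                "relative stride-length error (ratio):",
                f"  mean {m.mae:8.4f}   sd {m.sd_of_errors:8.4f}",
                f"  min  {m.min_error:8.4f}   max {m.max_error:8.4f}",
            ]
        return "\n".join(lines)

    def plot_diagnostics(self, ax=None):
        """Estimated vs reference lengths per stride (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.estimated_lengths, "o-", label="estimated")
        if self.reference_lengths is not None:
            ax.plot(self.reference_lengths, "s--", label="reference")
        ax.set_xlabel("stride")
        ax.set_ylabel("length (m)")
        ax.set_title(f"stride lengths — {self.model.mode}")
        ax.legend()
        return ax


@dataclass
class StrideLengthModel:
    """Stride-length estimator over one walking record.

    Parameters
    ----------
    sequence, events
        The IMU record and the stride-delimiting event indices.
    reference_lengths
        Optional per-stride ground-truth lengths (m), one per stride.
    mode
        ``origin``, ``ekf`` or ``mekf`` (see module docstring).
    axis
        Measurement channel, default ``az``.
    wavelet_cfg, smoother
        Preprocessing front-end settings (filtered modes only).
    filter_cfg
        Kalman-filter tunables; ``ekf`` mode overrides the gain boost and
        sign-flip off. Each stride is filtered from a fresh state
        ``x0 = [0, 0, z₀]`` (cyclic-gait reinitialisation).
    """

    sequence: ImuSequence
    events: StrideEventIndex
    reference_lengths: np.ndarray | None = None
    mode: str = "mekf"
    axis: str = "az"
    wavelet_cfg: WaveletConfig = field(default_factory=WaveletConfig)
    smoother: bool = True
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(
                f"invalid mode {self.mode!r}; valid modes are {', '.join(MODES)}"
            )
        self.events.validate_against(len(self.sequence))
        if self.reference_lengths is not None:
            self.reference_lengths = np.asarray(self.reference_lengths, dtype=float)
            if len(self.reference_lengths) != self.events.n_strides:
                raise ValueError("one reference length per stride is required")
        if self.filter_cfg.dt != self.sequence.dt:
            self.filter_cfg = replace(self.filter_cfg, dt=self.sequence.dt)

    @classmethod
    def from_files(
        cls,
        imu_path: str | Path,
        events_path: str | Path,
        truth_path: str | Path | None = None,
        dt: float = 0.02,
        one_based: bool = False,
        scale: float = 1.0,
        **kwargs,
    ) -> "StrideLengthModel":
        seq = read_imu_csv(imu_path, dt=dt, scale=scale)
        events = read_stride_events(events_path, len(seq), one_based=one_based)
        refs = None
        if truth_path is not None:
            truth = pd.read_csv(truth_path)
            refs = truth["reference_length"].to_numpy(dtype=float)
        return cls(sequence=seq, events=events, reference_lengths=refs, **kwargs)

    def _effective_filter_cfg(self) -> FilterConfig:
        if self.mode == "ekf":
            return replace(
                self.filter_cfg, boost_factor=1.0, sign_flip_enabled=False
            )
        return self.filter_cfg

    def preprocessed_channel(self) -> np.ndarray:
        """The measurement channel after the preprocessing front end
        (identity in origin mode)."""
        raw = self.sequence.channel(self.axis)
        if self.mode == "origin":
            return raw
        return denoise_and_smooth(raw, self.wavelet_cfg, smoother=self.smoother)

    def fit(self) -> StrideLengthResults:
        """Run the pipeline and return the per-stride results."""
        processed = self.preprocessed_channel()
        work_seq = dataclasses.replace(
            self.sequence,
            **{self.axis: processed},
            timestamps=None,
        )
        segments = segment_strides(work_seq, self.events, channel=self.axis)

        cfg = self._effective_filter_cfg()
        filtered_states: list[list[FilterState]] | None
        lengths = []
        if self.mode == "origin":
            filtered_states = None
            for seg in segments:
                lengths.append(
                    double_integrate_length(seg.samples, self.sequence.dt)
                    * cfg.calibration
                )
        else:
            filtered_states = []
            for seg in segments:
                seg_cfg = replace(
                    cfg, x0=np.array([0.0, 0.0, seg.samples[0]])
                )
                states = run_mekf(seg.samples, seg_cfg)
                filtered_states.append(states)
                lengths.append(stride_length_from_states(states, seg_cfg))

        estimates = []
        for i, L in enumerate(lengths):
            ref = (
                float(self.reference_lengths[i])
                if self.reference_lengths is not None
                else None
            )
            estimates.append(
                StrideEstimate(stride_id=i, estimated_length=L, reference_length=ref)
            )
        metrics = None
        if self.reference_lengths is not None and np.all(self.reference_lengths != 0):
            metrics = error_summary(self.reference_lengths, np.asarray(lengths))
        return StrideLengthResults(
            model=self,
            estimates=estimates,
            segments=segments,
            filtered_states=filtered_states,
            metrics=metrics,
        )
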