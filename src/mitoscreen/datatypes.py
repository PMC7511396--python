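"""Core containers shared by every pipeline stage.

An :class:`ImageStack` is the raw acquisition: a ``[T, Z, C, Y, X]`` array of
non-negative intensities together with the physical calibration needed to
report areas in µm² and time in minutes.  A :class:`LabelMap` is an integer
segmentation of one object class (nuclei, cells, mitochondria, lysosomes,
spots) on the 2-D maximum-projection grid of a single frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

OBJECT_CLASSES = ("nucleus", "cell", "mitochondrion", "lysosome", "spot")


@dataclass
class ImageStack:
    """Multi-channel, multi-z, optionally multi-timepoint fluorescence stack.

    Parameters
    ----------
    pixels
        Array of shape ``(T, Z, C, Y, X)``, non-negative intensities.
    pixel_size
        Lateral calibration in µm / pixel.
    frame_interval
        Time between frames in minutes (18 for the live mitophagy assay).
    channel_names
        One name per channel, e.g. ``["nuclei", "mitochondria", "lysosomes"]``.
    """

    pixels: np.ndarray
    pixel_size: float
    frame_interval: float = 18.0
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 5:
            raise ValueError(
                f"pixels must be 5-D [T, Z, C, Y, X], got {self.pixels.ndim}-D"
            )
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("intensities must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        t, z, c = self.pixels.shape[:3]
        if t < 1 or z < 1:
            raise ValueError("need T >= 1 and Z >= 1")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(c)]
        if len(self.channel_names) != c:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {c} channels"
            )

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not present; have {self.channel_names}"
            ) from None

    def to_tiff(self, path) -> None:
        """Write as OME-TIFF with TZCYX axes and calibration metadata."""
        tifffile.imwrite(
            path,
            self.pixels,
            ome=True,
            metadata={
                "axes": "TZCYX",
                "Channel": {"Name": list(self.channel_names)},
                "PhysicalSizeX": self.pixel_size,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeY": self.pixel_size,
                "PhysicalSizeYUnit": "µm",
                "TimeIncrement": self.frame_interval,
                "TimeIncrementUnit": "min",
            },
        )

    @classmethod
    def from_tiff(
        cls,
        path,
        pixel_size: float | None = None,
        frame_interval: float | None = None,
        channel_names: list[str] | None = None,
    ) -> "ImageStack":
        """Read an OME-TIFF / TIFF written by :meth:`to_tiff` (or compatible).

        Missing axes are restored as singletons; explicit arguments override
        whatever metadata the file carries.
        """
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = series.axes.upper().replace("S", "C").replace("Q", "Z")
            # pad to TZCYX
            for ax in "TZC":
                if ax not in axes:
                    data = np.expand_dims(data, 0)
                    axes = ax + axes
            order = [axes.index(ax) for ax in "TZCYX"]
            data = np.transpose(data, order)
            meta_px, meta_dt, meta_ch = 1.0, 18.0, None
            if tf.ome_metadata:
                import re

                m = re.search(r'PhysicalSizeX="([\d.eE+-]+)"', tf.ome_metadata)
                if m:
                    meta_px = float(m.group(1))
                m = re.search(r'TimeIncrement="([\d.eE+-]+)"', tf.ome_metadata)
                if m:
                    meta_dt = float(m.group(1))
                names = re.findall(r'<Channel[^>]*Name="([^"]+)"', tf.ome_metadata)
                if names:
                    meta_ch = names
        return cls(
            pixels=data,
            pixel_size=pixel_size if pixel_size is not None else meta_px,
            frame_interval=frame_interval if frame_interval is not None else meta_dt,
            channel_names=channel_names or meta_ch or [],
        )


@dataclass
class LabelMap:
    """Integer-labelled segmentation of one object class on one frame.

    ``labels`` is ``(Y, X)`` with 0 = background and objects numbered by
    contiguous positive integers.
    """

    labels: np.ndarray
    object_class: str
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D [Y, X]")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.object_class not in OBJECT_CLASSES:
            raise ValueError(
                f"object_class must be one of {OBJECT_CLASSES}, got {self.object_class!r}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    @property
    def ids(self) -> np.ndarray:
        return np.unique(self.labels[self.labels > 0])

    def to_tiff(self, path) -> None:
        mx = int(self.labels.max()) if self.labels.size else 0
        dtype = np.uint16 if mx < 2**16 else np.uint32
        tifffile.imwrite(path, self.labels.astype(dtype))


def relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    """Renumber positive labels to 1..n preserving order of first appearance
    in sorted label value."""
    out = np.zeros_like(labels)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new
    return out
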