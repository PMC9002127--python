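"""Optional adapter for the HC18 grand-challenge annotation layout.

HC18 ships a CSV (``filename, pixel size(mm)`` and, for the training
set, the manual HC) next to annotation images that draw the expert
ellipse as a bright contour on black.  This adapter fits an ellipse to
each contour by algebraic least squares and emits the package's internal
annotation objects.  It is a convenience for users with the real data;
nothing in the package's tests or pipeline depends on it.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.measure import EllipseModel

from .encoding import Annotation
from .geometry import Ellipse

__all__ = ["fit_ellipse_to_contour", "load_hc18_annotations"]

log = logging.getLogger(__name__)


def fit_ellipse_to_contour(contour_image: np.ndarray) -> Ellipse:
    """Least-squares ellipse fit to the bright pixels of a contour image.

    The fitted angle is normalized to the package convention: semi-axes
    sorted so a >= b and theta (short axis vs. vertical == major axis
    vs. horizontal) wrapped into [0, 180).
    """
    ys, xs = np.nonzero(np.asarray(contour_image) > 127)
    if len(xs) < 10:
        raise ValueError("contour image has too few bright pixels for a fit")
    model = EllipseModel()
    if not model.estimate(np.column_stack([xs, ys]).astype(float)):
        raise ValueError("ellipse fit did not converge")
    (xc, yc), (a, b), theta_rad = model.center, model.axis_lengths, model.theta
    psi = math.degrees(theta_rad)
    if b > a:
        a, b = b, a
        psi += 90.0
    return Ellipse(cx=float(xc), cy=float(yc), a=float(a), b=float(b), theta=psi % 180.0)


def load_hc18_annotations(csv_path: str | Path, annotation_images_dir: str | Path) -> list[Annotation]:
    """Read an HC18-layout CSV + annotation-contour directory.

    Malformed rows and unreadable or unfittable images are skipped with
    a logged count.  Returns annotations in the internal dialect (a, b
    are semi-axes in pixels).
    """
    csv_path = Path(csv_path)
    img_dir = Path(annotation_images_dir)
    try:
        df = pd.read_csv(csv_path)
    except FileNotFoundError:
        raise
    if df.empty or not img_dir.is_dir():
        log.warning("no HC18 annotations found (csv rows=%d, dir exists=%s)",
                    len(df), img_dir.is_dir())
        return []
    px_col = next((c for c in df.columns if "pixel" in c.lower()), df.columns[1])
    out: list[Annotation] = []
    skipped = 0
    for _, row in df.iterrows():
        try:
            fname = str(row.iloc[0])
            pixel_size = float(row[px_col])
            stem = fname.rsplit(".", 1)[0]
            candidates = [img_dir / f"{stem}_Annotation.png", img_dir / fname]
            path = next((p for p in candidates if p.exists()), None)
            if path is None:
                raise FileNotFoundError(f"no annotation image for {fname}")
            contour = np.asarray(Image.open(path).convert("L"))
            ellipse = fit_ellipse_to_contour(contour)
            out.append(Annotation(image_id=stem, ellipse=ellipse,
                                  pixel_size_mm=pixel_size, is_negative=False))
        except Exception as exc:  # noqa: BLE001 - per-file robustness contract
            skipped += 1
            log.warning("skipping HC18 row %r: %s", row.iloc[0] if len(row) else "?", exc)
    if skipped:
        log.warning("skipped %d HC18 rows", skipped)
    return out
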