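"""Connected-component filtering of predicted segmentation masks.

For each non-background class independently, connected components are
labelled, the largest component's pixel count is taken as reference, and
every component whose size is at least ``threshold_fraction`` (default
0.60) of that reference is retained; all other pixels of the class are
reset to background. This removes spurious islands while preserving any
structure of comparable size to the main one.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from sklearn.base import BaseEstimator, TransformerMixin

from .datamodel import FOREGROUND_CLASSES, LabelMask

_STRUCTURES = {
    4: ndi.generate_binary_structure(2, 1),
    8: ndi.generate_binary_structure(2, 2),
}


class ComponentFilter(BaseEstimator, TransformerMixin):
    """Size-relative connected-component filter (stateless transformer).

    Parameters
    ----------
    threshold_fraction : float in (0, 1], default 0.60
        A component is kept iff its pixel count is >= this fraction of
        the largest component of its class ("at least 60%" keeps a
        component exactly at the boundary).
    connectivity : {4, 8}, default 8
        Pixel adjacency defining components; 8 joins diagonal neighbours.
    """

    def __init__(self, threshold_fraction: float = 0.60, connectivity: int = 8):
        self.threshold_fraction = threshold_fraction
        self.connectivity = connectivity

    def _validate(self) -> np.ndarray:
        if not (0.0 < self.threshold_fraction <= 1.0):
            raise ValueError(f"threshold_fraction must be in (0, 1], got {self.threshold_fraction}")
        if self.connectivity not in _STRUCTURES:
            raise ValueError(f"connectivity must be 4 or 8, got {self.connectivity}")
        return _STRUCTURES[self.connectivity]

    def fit(self, X=None, y=None) -> "ComponentFilter":
        """No-op; the filter learns nothing. Validates parameters."""
        self._validate()
        self.n_features_in_ = 0
        return self

    def transform(self, X):
        """Filter one mask (``LabelMask`` or 2D integer array) or a list of them."""
        if isinstance(X, (list, tuple)):
            return [self._filter_one(m) for m in X]
        return self._filter_one(X)

    def _filter_one(self, mask):
        structure = self._validate()
        is_labelmask = isinstance(mask, LabelMask)
        labels = mask.labels if is_labelmask else np.asarray(mask)
        out = labels.copy()
        for class_code in FOREGROUND_CLASSES:
            binary = labels == class_code
            if not binary.any():
                continue
            comp, n_comp = ndi.label(binary, structure=structure)
            sizes = np.bincount(comp.ravel())[1:]  # component ids are 1..n_comp
            cutoff = self.threshold_fraction * sizes.max()
            drop = np.nonzero(sizes < cutoff)[0] + 1
            if drop.size:
                out[np.isin(comp, drop)] = 0
        return mask.with_labels(out) if is_labelmask else out


def filter_components(mask, threshold_fraction: float = 0.60, connectivity: int = 8):
    """Functional form of :class:`ComponentFilter` for a single mask."""
    return ComponentFilter(threshold_fraction, connectivity).transform(mask)
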