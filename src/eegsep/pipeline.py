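"""Convenience glue: cohort -> per-subject sub-band tensors.

Thin orchestration over the synthetic, preprocessing and wavelet stages used
by the CLI, the LOOCV driver and the test/acceptance harnesses.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .preprocessing import EEGRecording, bandpass_filter, segment_epochs
from .synthetic import CohortSpec, generate_cohort
from .wavelet import build_epoch_tensor


def subject_subband_tensors(
    spec: CohortSpec,
    cohort: Optional[Sequence[Tuple[str, str, EEGRecording]]] = None,
    apply_bandpass: bool = False,
    max_epochs: Optional[int] = None,
    dtype=np.float32,
) -> Tuple[List[str], List[str], Dict[str, np.ndarray]]:
    """Cohort -> (subject_ids, class_labels, {subject_id: tensor values}).

    When ``cohort`` is omitted it is generated from ``spec`` in epoch-ready
    mode (already band-limited, so filtering is skipped unless requested).
    """
    if cohort is None:
        cohort = generate_cohort(spec)
    ids: List[str] = []
    labels: List[str] = []
    tensors: Dict[str, np.ndarray] = {}
    for sid, cls, rec in cohort:
        if apply_bandpass:
            rec = bandpass_filter(rec)
        ep = segment_epochs(rec, spec.epoch_seconds,
                            max_epochs=max_epochs, subject_id=sid,
                            class_label=cls)
        t = build_epoch_tensor(ep, expected_samples=spec.epoch_samples,
                               dtype=dtype)
        ids.append(sid)
        labels.append(cls)
        tensors[sid] = t.values
    return ids, labels, tensors
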