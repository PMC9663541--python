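"""Small shared helpers."""

from __future__ import annotations

# Labels that conventionally denote the baseline (unmodulated) condition.
_BASELINE_NAMES = ("low", "baseline", "base", "control", "ctrl", "off", "0")


def order_contrast_labels(labels, baseline_label=None):
    """Return the two contrast labels as (baseline, modulated).

    Which condition counts as baseline is an arbitrary labeling choice, but
    it must be applied consistently; when not given explicitly, a label with
    a conventional baseline name (e.g. "low") is preferred, falling back to
    the first label in sorted order.
    """
    labels = sorted(set(labels))
    if len(labels) != 2:
        raise ValueError(f"exactly two contrast conditions required, got {labels}")
    if baseline_label is None:
        preferred = [l for l in labels if str(l).lower() in _BASELINE_NAMES]
        baseline_label = preferred[0] if preferred else labels[0]
    if baseline_label not in labels:
        raise ValueError(f"baseline label {baseline_label!r} not among {labels}")
    other = labels[0] if labels[1] == baseline_label else labels[1]
    return baseline_label, other
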