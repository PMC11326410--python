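"""Names of the nine per-run eye measures used throughout the analysis."""

#: three basic eye measures plus the six BIPR peak parameters
MEASURES = [
    "blink_rate",
    "blink_duration",
    "pupil_size",
    "d_time",
    "d_amp",
    "c_time",
    "c_amp",
    "dc_time_diff",
    "dc_peakdrop",
]

#: vigilance states after merging drowsy and very drowsy runs
STATES = ["vigilant", "all_drowsy"]


def merge_drowsy(state: str) -> str:
    """Map raw run states onto the two analysis states."""
    if state in ("drowsy", "very_drowsy"):
        return "all_drowsy"
    return state
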