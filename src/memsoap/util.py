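"""Small shared helpers."""

from __future__ import annotations

import hashlib
import json

from .errors import ParameterError


def inclusive_frame_count(total_ns: float, interval_ns: float) -> int:
    """Number of analysis frames when sampling every ``interval_ns`` from 0 to
    ``total_ns`` inclusive: e.g. 1000 ns every 10 ns -> 101 frames."""
    if interval_ns <= 0 or total_ns < 0:
        raise ParameterError("need total_ns >= 0 and interval_ns > 0")
    return int(round(total_ns / interval_ns)) + 1


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
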