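"""Run configuration (YAML) and stderr logging with per-stage timing."""

from __future__ import annotations

import contextlib
import logging
import sys
import time

import yaml

logger = logging.getLogger("landgen")


def setup_logging(level: int = logging.INFO) -> None:
    """Route package logs to stderr (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)


@contextlib.contextmanager
def stage(name: str):
    """Log wall-clock time of a pipeline stage."""
    t0 = time.perf_counter()
    logger.info("stage %s: start", name)
    try:
        yield
    finally:
        logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration file must contain a YAML mapping")
    return cfg
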