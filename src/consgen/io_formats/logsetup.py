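"""Newline-delimited logging with level and timestamp."""

from __future__ import annotations

import logging

_FORMAT = "%(asctime)s %(levelname)s %(name)s: %(message)s"


def get_logger(name: str = "consgen", path: "str | None" = None,
               level: int = logging.INFO) -> logging.Logger:
    """Return a configured logger; optionally also log to ``path``."""
    logger = logging.getLogger(name)
    logger.setLevel(level)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter(_FORMAT))
        logger.addHandler(handler)
    if path is not None and not any(
        isinstance(h, logging.FileHandler)
        and getattr(h, "baseFilename", None) == str(path)
        for h in logger.handlers
    ):
        fh = logging.FileHandler(path)
        fh.setFormatter(logging.Formatter(_FORMAT))
        logger.addHandler(fh)
    return logger
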