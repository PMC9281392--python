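"""Fixed-schema CSV scalar log: step, KE, PE, E, T, density, volume."""

from __future__ import annotations

import csv

COLUMNS = ("step", "KE", "PE", "E", "T", "density", "volume")


class ScalarLog:
    """Appends one CSV row per record, flushing at a configurable interval."""

    def __init__(self, path, flush_every: int = 100):
        self.path = path
        self.flush_every = flush_every
        self._fh = open(path, "w", newline="")
        self._writer = csv.writer(self._fh)
        self._writer.writerow(COLUMNS)
        self._count = 0

    def log(self, step, ke, pe, e, temperature, density, vol) -> None:
        self._writer.writerow(
            [step]
            + [f"{v:.12g}" for v in (ke, pe, e, temperature, density, vol)]
        )
        self._count += 1
        if self._count % self.flush_every == 0:
            self._fh.flush()

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
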