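"""MR-appearance to CT-appearance intensity translation of 2D cine frames.

The motion model is trained on CT-appearance pixel values from the planning
4D series, while the intra-treatment stream arrives with MR appearance; this
module bridges the two pixel-value domains while preserving geometry.

Two modes are provided:

* ``lookup`` — a deterministic monotone lookup fitted to *paired* samples by
  isotonic regression.  Paired data only exist for the phantom (real MR/CT
  patient images are unpaired); this is the default mode throughout the test
  suite because it is exact and CPU-cheap.
* ``cycle-adversarial`` — trained from *unpaired* image sets with the
  cycle-consistent adversarial objective (two generators, two
  discriminators, least-squares adversarial loss + cycle and identity L1
  terms).  The generators are learnable monotone piecewise-linear intensity
  curves and the discriminators small per-pixel MLPs: intensity translation
  between renderings of the same anatomy is pixelwise and monotone, so this
  architecture trains reliably on one CPU and cannot move anatomy by
  construction.

Preprocessing contract: intensities are percentile-clipped (0.2nd-99.8th,
wide enough to keep the sparse tumor tail unclipped) and scaled to [0, 1]
with constants frozen at training time and applied identically at inference.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.isotonic import IsotonicRegression

from ._nets import Adam, MonotoneCurve, TinyMLP
from .core import CineFrame
from . import phantom as _phantom


class TranslationError(ValueError):
    pass


@dataclass
class TranslationModel:
    """Serializable MR->CT intensity translator with deterministic inference."""

    mode: str                                  # "lookup" | "cycle-adversarial"
    table_x: np.ndarray                        # lookup grid (input intensity)
    table_y: np.ndarray                        # lookup values (output intensity)
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.table_x = np.asarray(self.table_x, dtype=np.float64)
        self.table_y = np.asarray(self.table_y, dtype=np.float64)
        if self.table_x.ndim != 1 or self.table_x.shape != self.table_y.shape:
            raise ValueError("lookup table must be two equal-length 1D arrays")
        if np.any(np.diff(self.table_x) <= 0):
            raise ValueError("lookup grid must be strictly increasing")

    def apply(self, data: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(data, dtype=np.float64),
                         self.table_x, self.table_y).astype(np.float32)

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), table_x=self.table_x, table_y=self.table_y)
        path.with_suffix(".json").write_text(json.dumps(
            {"kind": "translation_model", "mode": self.mode, **self.manifest},
            indent=2, sort_keys=True, default=str))

    @classmethod
    def load(cls, path) -> "TranslationModel":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        with np.load(path.with_suffix(".npz")) as z:
            table_x, table_y = z["table_x"], z["table_y"]
        mode = manifest.pop("mode")
        manifest.pop("kind", None)
        return cls(mode=mode, table_x=table_x, table_y=table_y, manifest=manifest)


def translate(model: TranslationModel, frame: CineFrame) -> CineFrame:
    """Translate one MR-appearance cine frame to CT appearance.

    Geometry, timestamp and frame index are preserved; only pixel values
    change.  Inference is deterministic given the model.
    """
    if frame.modality != "mr":
        raise TranslationError(f"expected an MR-appearance frame, got {frame.modality!r}")
    expected = model.manifest.get("image_shape")
    if expected is not None and tuple(expected) != frame.shape:
        raise TranslationError(f"frame shape {frame.shape} does not match model {tuple(expected)}")
    return frame.with_data(model.apply(frame.data), modality="ct")


# ---------------------------------------------------------------------------
# lookup mode (paired samples; phantom only)
# ---------------------------------------------------------------------------

def fit_lookup(mr_samples: np.ndarray, ct_samples: np.ndarray,
               n_bins: int = 512, residual_warn_rel: float = 0.05) -> TranslationModel:
    """Fit a monotone MR->CT lookup from paired samples by isotonic regression.

    A best monotone fit is always returned; if the paired relation is not
    monotone the relative residual is reported via a warning and recorded in
    the manifest.
    """
    mr = np.asarray(mr_samples, dtype=np.float64).ravel()
    ct = np.asarray(ct_samples, dtype=np.float64).ravel()
    if mr.shape != ct.shape or mr.size == 0:
        raise TranslationError("paired samples must be equal-size and non-empty")
    if np.ptp(mr) == 0:
        raise TranslationError("degenerate (constant) MR samples")
    iso = IsotonicRegression(increasing="auto", out_of_bounds="clip")
    fitted = iso.fit_transform(mr, ct)
    resid = float(np.sqrt(np.mean((fitted - ct) ** 2)))
    rng_ct = float(np.ptp(ct)) or 1.0
    if resid > residual_warn_rel * rng_ct:
        warnings.warn(
            f"paired MR/CT relation is not monotone: isotonic residual RMS {resid:.3g} "
            f"({resid / rng_ct:.1%} of CT range); returning the best monotone fit",
            stacklevel=2)
    grid = np.quantile(mr, np.linspace(0.0, 1.0, n_bins))
    grid = np.unique(grid)
    if grid.size < 2:
        raise TranslationError("degenerate MR sample distribution")
    vals = iso.predict(grid)
    return TranslationModel(
        mode="lookup", table_x=grid, table_y=vals,
        manifest={"n_samples": int(mr.size), "residual_rms": resid})


def exact_phantom_model(config: _phantom.PhantomConfig,
                        lo: float = 0.0, hi: float = 1200.0,
                        n: int = 4096) -> TranslationModel:
    """Translator built from the phantom's exact tissue intensity map
    (the known inverse of the MR rendering; noise-free construction)."""
    _, mr_to_ct = _phantom.intensity_maps(config)
    grid = np.linspace(lo, hi, n)
    return TranslationModel(mode="lookup", table_x=grid, table_y=mr_to_ct(grid),
                            manifest={"source": "phantom-exact"})


# ---------------------------------------------------------------------------
# cycle-adversarial mode (unpaired image sets)
# ---------------------------------------------------------------------------

@dataclass
class CycleTrainConfig:
    epochs: int = 300
    batch_images: int = 4
    pixels_per_image: int = 1024
    lr: float = 2e-3
    lambda_cycle: float = 10.0
    lambda_identity: float = 0.5
    n_knots: int = 32
    norm_percentiles: tuple[float, float] = (0.2, 99.8)
    seed: int = 0


def _norm_constants(images: np.ndarray, percentiles=(0.2, 99.8)) -> tuple[float, float]:
    lo, hi = np.percentile(images, list(percentiles))
    if hi <= lo:
        raise TranslationError("degenerate image set (no intensity range)")
    return float(lo), float(hi)


def _lsgan_d_loss_grad(d_real, d_fake):
    n = d_real.size + d_fake.size
    loss = 0.5 * (np.mean((d_real - 1.0) ** 2) + np.mean(d_fake ** 2))
    return loss, (d_real - 1.0) / d_real.size, d_fake / d_fake.size


def train_translation(mr_images, ct_images, config: CycleTrainConfig | None = None,
                      ) -> TranslationModel:
    """Train the unpaired cycle-adversarial MR->CT translator.

    ``mr_images`` and ``ct_images`` are sequences of 2D arrays (need not be
    paired nor from the same cross-sections).  Returns the MR->CT generator
    wrapped as a :class:`TranslationModel`; the training manifest records the
    loss curve, epochs, seed and image counts.  All randomness is seeded.
    """
    config = config or CycleTrainConfig()
    mr_list = [np.asarray(a, dtype=np.float64) for a in mr_images]
    ct_list = [np.asarray(a, dtype=np.float64) for a in ct_images]
    if not mr_list or not ct_list:
        raise TranslationError("both image sets must be non-empty")
    if len({a.shape for a in mr_list + ct_list}) != 1:
        raise TranslationError("all images must share one shape after preprocessing")
    rng = np.random.default_rng(config.seed)
    mr_lo, mr_hi = _norm_constants(np.stack(mr_list), config.norm_percentiles)
    ct_lo, ct_hi = _norm_constants(np.stack(ct_list), config.norm_percentiles)
    norm = {"mr": (mr_lo, mr_hi), "ct": (ct_lo, ct_hi)}

    g_mr2ct = MonotoneCurve(config.n_knots, rng)      # normalized mr -> normalized ct
    g_ct2mr = MonotoneCurve(config.n_knots, rng)
    d_ct = TinyMLP((1, 16, 16, 1), rng)
    d_mr = TinyMLP((1, 16, 16, 1), rng)
    opt_g = Adam(g_mr2ct.params + g_ct2mr.params, lr=config.lr)
    opt_d = Adam(d_ct.params + d_mr.params, lr=config.lr)

    def sample_pixels(images, k):
        img = images[rng.integers(len(images))]
        flat = img.ravel()
        return flat[rng.integers(flat.size, size=k)]

    def normalize(x, dom):
        lo, hi = norm[dom]
        return np.clip((x - lo) / (hi - lo), 0.0, 1.0)

    loss_curve = []
    for _ in range(config.epochs):
        epoch_losses = []
        for _ in range(config.batch_images):
            u_mr = normalize(sample_pixels(mr_list, config.pixels_per_image), "mr")
            u_ct = normalize(sample_pixels(ct_list, config.pixels_per_image), "ct")

            # --- discriminators -------------------------------------------
            fake_ct = g_mr2ct.forward(u_mr)
            fake_mr = g_ct2mr.forward(u_ct)
            loss_d = 0.0
            grads_d = []
            for disc, real, fake in ((d_ct, u_ct, fake_ct), (d_mr, u_mr, fake_mr)):
                dr = disc.forward(real[:, None])
                _, g_real, _ = _lsgan_d_loss_grad(dr, np.zeros(1))
                gr, _ = disc.backward(g_real)
                df = disc.forward(fake[:, None])
                l, _, g_fake = _lsgan_d_loss_grad(np.ones(1), df)
                gf, _ = disc.backward(g_fake)
                grads_d.extend([a + b for a, b in zip(gr, gf)])
                loss_d += l
            opt_d.step(grads_d)

            # --- generators ------------------------------------------------
            # adversarial: G_mr2ct fools d_ct; cycle both ways; identity terms
            fake_ct = g_mr2ct.forward(u_mr)
            d_out = d_ct.forward(fake_ct[:, None])
            adv1 = float(np.mean((d_out - 1.0) ** 2))
            _, g_in = d_ct.backward(2.0 * (d_out - 1.0) / d_out.size)
            grad_g1 = g_mr2ct.backward(g_in.ravel())

            cyc_mr = g_ct2mr.forward(fake_ct)
            cyc1 = float(np.mean(np.abs(cyc_mr - u_mr)))
            g_cyc = config.lambda_cycle * np.sign(cyc_mr - u_mr) / cyc_mr.size
            grad_g2_from_cyc = g_ct2mr.backward(g_cyc)
            # d cyc / d fake_ct through the second curve's input
            v = g_ct2mr.knot_values()
            slope2 = np.diff(v) * g_ct2mr.n_knots
            i0, frac = g_ct2mr._cache
            g_fake_ct_cyc = g_cyc * slope2[np.minimum(i0, g_ct2mr.n_knots - 1)]
            grad_g1_cyc = g_mr2ct.backward(g_fake_ct_cyc)

            fake_mr = g_ct2mr.forward(u_ct)
            d_out2 = d_mr.forward(fake_mr[:, None])
            adv2 = float(np.mean((d_out2 - 1.0) ** 2))
            _, g_in2 = d_mr.backward(2.0 * (d_out2 - 1.0) / d_out2.size)
            grad_g2_adv = g_ct2mr.backward(g_in2.ravel())

            cyc_ct = g_mr2ct.forward(fake_mr)
            cyc2 = float(np.mean(np.abs(cyc_ct - u_ct)))
            g_cyc2 = config.lambda_cycle * np.sign(cyc_ct - u_ct) / cyc_ct.size
            grad_g1_from_cyc2 = g_mr2ct.backward(g_cyc2)
            v1 = g_mr2ct.knot_values()
            slope1 = np.diff(v1) * g_mr2ct.n_knots
            i0b, _ = g_mr2ct._cache
            g_fake_mr_cyc = g_cyc2 * slope1[np.minimum(i0b, g_mr2ct.n_knots - 1)]
            grad_g2_cyc2 = g_ct2mr.backward(g_fake_mr_cyc)

            # identity: G_mr2ct(ct) ~ ct, G_ct2mr(mr) ~ mr
            id_ct = g_mr2ct.forward(u_ct)
            idl1 = float(np.mean(np.abs(id_ct - u_ct)))
            grad_g1_id = g_mr2ct.backward(
                config.lambda_identity * np.sign(id_ct - u_ct) / id_ct.size)
            id_mr = g_ct2mr.forward(u_mr)
            idl2 = float(np.mean(np.abs(id_mr - u_mr)))
            grad_g2_id = g_ct2mr.backward(
                config.lambda_identity * np.sign(id_mr - u_mr) / id_mr.size)

            grads_g1 = [a + b + c + d for a, b, c, d in
                        zip(grad_g1, grad_g1_cyc, grad_g1_from_cyc2, grad_g1_id)]
            grads_g2 = [a + b + c + d for a, b, c, d in
                        zip(grad_g2_adv, grad_g2_from_cyc, grad_g2_cyc2, grad_g2_id)]
            opt_g.step(grads_g1 + grads_g2)

            total = (adv1 + adv2 + config.lambda_cycle * (cyc1 + cyc2)
                     + config.lambda_identity * (idl1 + idl2) + loss_d)
            if not np.isfinite(total):
                raise TranslationError("non-finite loss during adversarial training")
            epoch_losses.append(total)
        loss_curve.append(float(np.mean(epoch_losses)))

    # bake the trained generator into a lookup table over the MR input range
    grid = np.linspace(mr_lo - 0.05 * (mr_hi - mr_lo), mr_hi + 0.05 * (mr_hi - mr_lo), 2048)
    u = np.clip((grid - mr_lo) / (mr_hi - mr_lo), 0.0, 1.0)
    vals = g_mr2ct.forward(u) * (ct_hi - ct_lo) + ct_lo
    # enforce a strictly increasing grid/value table
    vals = np.maximum.accumulate(vals)
    return TranslationModel(
        mode="cycle-adversarial", table_x=grid, table_y=vals,
        manifest={
            "epochs": config.epochs, "seed": config.seed,
            "n_mr_images": len(mr_list), "n_ct_images": len(ct_list),
            "image_shape": list(mr_list[0].shape),
            "loss_curve": loss_curve,
            "norm_mr": [mr_lo, mr_hi], "norm_ct": [ct_lo, ct_hi],
        })
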