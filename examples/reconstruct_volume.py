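"""Reconstruct an axis-aligned volume from raw sheared tiles and score
it against the known phantom truth.

Chain: flat-field correction (mode-based weight matrix from the
soil-texture channel) -> inverse-shear deskew -> phase-correlation tile
registration -> Laplacian-pyramid stitching -> Richardson-Lucy
deconvolution with the light-sheet PSF.
"""

from rhizolight.protocols import reconstruction_fidelity

result = reconstruction_fidelity(seed=11)

for channel, r in sorted(result["pearson_r"].items()):
    print(f"{channel:9s} voxelwise Pearson r vs truth: {r:.4f}")
errs = result["centroid_errors_voxels"]
print(f"grain centroid error over {result['n_grains']} grains: "
      f"max {max(errs):.3f} voxels, mean {sum(errs)/len(errs):.3f} voxels")
# r >= 0.98 and sub-voxel centroid accuracy mean the 45-degree scan
# geometry, stitching and deconvolution introduce no systematic distortion
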