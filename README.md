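# endoguide

An in-silico testbed for camera-based augmented-reality needle guidance.
It synthesizes CT-like volumes of three experimental scenarios (a rigid
trunk phantom with five bar targets, a breathing porcine-like body with
three implanted point targets, and a cadaver-like body with two spherical
liver lesions), runs the full guidance chain on them — threshold
segmentation, PCA marker-coordinate extraction, pinhole-camera pose
tracking of patient and needle-handle marker clusters, rigid CT-to-tracker
registration, tip-to-target distance readout — and reproduces the
corresponding accuracy experiments, including gated versus free-breathing
insertion.

No external data is needed: every input is generated by the scene factory.

## Layout

| module | role |
| --- | --- |
| `endoguide.geometry` | rigid transforms, fiducial sets, SVD point-set registration, TRE |
| `endoguide.scene` | scenario construction (distance-table embedding, surface tags, needle assembly) and voxelization, NIfTI I/O |
| `endoguide.ctproc` | 26-connected threshold segmentation, PCA marker frames, target centroids |
| `endoguide.camera` | pinhole projection, simulated marker observation, pose estimation (homography/DLT init + Levenberg–Marquardt) |
| `endoguide.respiration` | raised-cosine respiratory motion, gated/free phase sampling |
| `endoguide.guidance` | planning stage, needle-tip math, AR overlay coordinates, the closed-loop insertion simulation |
| `endoguide.experiments` | the three scripted accuracy studies + distance-table statistics |
| `endoguide.cli` | `endoguide` command-line interface |

## CLI

```sh
# run an accuracy study and write a JSON report
endoguide run --scenario porcine --free --reps 100 --seed 0 --out report.json

# distance-table statistics (published table by default, or your CSV)
endoguide table1
endoguide table1 --in mytable.csv

# generate a synthetic scene: NIfTI volume + ground-truth CSV/YAML
endoguide synth --scenario anthro --out volume.nii

# planning stage only: recovered fiducial centroids to CSV
endoguide plan --scenario cadaver --out centroids.csv
```

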