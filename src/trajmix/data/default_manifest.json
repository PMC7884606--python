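[
 {
  "region_id": "gcc",
  "name": "Genu of corpus callosum",
  "fibre_class": "commissural",
  "depth_class": "deep"
 },
 {
  "region_id": "bcc",
  "name": "Body of corpus callosum",
  "fibre_class": "commissural",
  "depth_class": "deep"
 },
 {
  "region_id": "scc",
  "name": "Splenium of corpus callosum",
  "fibre_class": "commissural",
  "depth_class": "deep"
 },
 {
  "region_id": "tap",
  "name": "Tapetum",
  "fibre_class": "commissural",
  "depth_class": "deep"
 },
 {
  "region_id": "cst",
  "name": "Corticospinal tract",
  "fibre_class": "projection",
  "depth_class": "deep"
 },
 {
  "region_id": "cp",
  "name": "Cerebral peduncle",
  "fibre_class": "projection",
  "depth_class": "deep"
 },
 {
  "region_id": "alic",
  "name": "Anterior limb of internal capsule",
  "fibre_class": "projection",
  "depth_class": "deep"
 },
 {
  "region_id": "plic",
  "name": "Posterior limb of internal capsule",
  "fibre_class": "projection",
  "depth_class": "deep"
 },
 {
  "region_id": "rlic",
  "name": "Retrolenticular part of internal capsule",
  "fibre_class": "projection",
  "depth_class": "deep"
 },
 {
  "region_id": "acr",
  "name": "Anterior corona radiata",
  "fibre_class": "projection",
  "depth_class": "deep"
 },
 {
  "region_id": "scr",
  "name": "Superior corona radiata",
  "fibre_class": "projection",
  "depth_class": "deep"
 },
 {
  "region_id": "pcr",
  "name": "Posterior corona radiata",
  "fibre_class": "projection",
  "depth_class": "deep"
 },
 {
  "region_id": "ptr",
  "name": "Posterior thalamic radiation",
  "fibre_class": "projection",
  "depth_class": "deep"
 },
 {
  "region_id": "fx",
  "name": "Fornix (column and body)",
  "fibre_class": "projection",
  "depth_class": "deep"
 },
 {
  "region_id": "fxst",
  "name": "Fornix / stria terminalis",
  "fibre_class": "projection",
  "depth_class": "deep"
 },
 {
  "region_id": "ec",
  "name": "External capsule",
  "fibre_class": "association",
  "depth_class": "deep"
 },
 {
  "region_id": "cgc",
  "name": "Cingulum (cingulate gyrus)",
  "fibre_class": "association",
  "depth_class": "deep"
 },
 {
  "region_id": "cgh",
  "name": "Cingulum (hippocampal)",
  "fibre_class": "association",
  "depth_class": "deep"
 },
 {
  "region_id": "slf",
  "name": "Superior longitudinal fasciculus",
  "fibre_class": "association",
  "depth_class": "deep"
 },
 {
  "region_id": "sfo",
  "name": "Superior fronto-occipital fasciculus",
  "fibre_class": "association",
  "depth_class": "deep"
 },
 {
  "region_id": "ifo",
  "name": "Inferior fronto-occipital fasciculus",
  "fibre_class": "association",
  "depth_class": "deep"
 },
 {
  "region_id": "unc",
  "name": "Uncinate fasciculus",
  "fibre_class": "association",
  "depth_class": "deep"
 },
 {
  "region_id": "ss",
  "name": "Sagittal stratum",
  "fibre_class": "association",
  "depth_class": "deep"
 },
 {
  "region_id": "mb",
  "name": "Midbrain",
  "fibre_class": "brainstem",
  "depth_class": "deep"
 },
 {
  "region_id": "pons",
  "name": "Pons",
  "fibre_class": "brainstem",
  "depth_class": "deep"
 },
 {
  "region_id": "med",
  "name": "Medulla",
  "fibre_class": "brainstem",
  "depth_class": "deep"
 },
 {
  "region_id": "scp",
  "name": "Superior cerebellar peduncle",
  "fibre_class": "brainstem",
  "depth_class": "deep"
 },
 {
  "region_id": "mcp",
  "name": "Middle cerebellar peduncle",
  "fibre_class": "brainstem",
  "depth_class": "deep"
 },
 {
  "region_id": "sfwm",
  "name": "Superior frontal WM",
  "fibre_class": "superficial",
  "depth_class": "superficial"
 },
 {
  "region_id": "mfwm",
  "name": "Middle frontal WM",
  "fibre_class": "superficial",
  "depth_class": "superficial"
 },
 {
  "region_id": "ifwm",
  "name": "Inferior frontal WM",
  "fibre_class": "superficial",
  "depth_class": "superficial"
 },
 {
  "region_id": "lfowm",
  "name": "Lateral fronto-orbital WM",
  "fibre_class": "superficial",
  "depth_class": "superficial"
 },
 {
  "region_id": "mfowm",
  "name": "Middle fronto-orbital WM",
  "fibre_class": "superficial",
  "depth_class": "superficial"
 },
 {
  "region_id": "rgwm",
  "name": "Gyrus rectus WM",
  "fibre_class": "superficial",
  "depth_class": "superficial"
 },
 {
  "region_id": "prcwm",
  "name": "Precentral WM",
  "fibre_class": "superficial",
  "depth_class": "superficial"
 },
 {
  "region_id": "pocwm",
  "name": "Postcentral WM",
  "fibre_class": "superficial",
  "depth_class": "superficial"
 },
 {
  "region_id": "spwm",
  "name": "Superior parietal WM",
  "fibre_class": "superficial",
  "depth_class": "superficial"
 },
 {
  "region_id": "smwm",
  "name": "Supramarginal WM",
  "fibre_class": "superficial",
  "depth_class": "superficial"
 },
 {
  "region_id": "agwm",
  "name": "Angular WM",
  "fibre_class": "superficial",
  "depth_class": "superficial"
 },
 {
  "region_id": "pcuwm",
  "name": "Precuneus WM",
  "fibre_class": "superficial",
  "depth_class": "superficial"
 },
 {
  "region_id": "sowm",
  "name": "Superior occipital WM",
  "fibre_class": "superficial",
  "depth_class": "superficial"
 },
 {
  "region_id": "mowm",
  "name": "Middle occipital WM",
  "fibre_class": "superficial",
  "depth_class": "superficial"
 },
 {
  "region_id": "iowm",
  "name": "Inferior occipital WM",
  "fibre_class": "superficial",
  "depth_class": "superficial"
 },
 {
  "region_id": "cunwm",
  "name": "Cuneus WM",
  "fibre_class": "superficial",
  "depth_class": "superficial"
 },
 {
  "region_id": "stwm",
  "name": "Superior temporal WM",
  "fibre_class": "superficial",
  "depth_class": "superficial"
 },
 {
  "region_id": "mtwm",
  "name": "Middle temporal WM",
  "fibre_class": "superficial",
  "depth_class": "superficial"
 },
 {
  "region_id": "itwm",
  "name": "Inferior temporal WM",
  "fibre_class": "superficial",
  "depth_class": "superficial"
 },
 {
  "region_id": "fuswm",
  "name": "Fusiform WM",
  "fibre_class": "superficial",
  "depth_class": "superficial"
 }
]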