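{
 "comment": "Synthetic reference tree: right-linear overvaluation tree with the published cutpoints 1.25/3.75/4.75/5.75 defining five ordered severity groups. Built from the printed thresholds only; node fits and statistics are not part of the fixture.",
 "covariates": ["overvaluation"],
 "config": null,
 "root": {
  "n": 1013, "depth": 0, "fit": null,
  "split": {"covariate": "overvaluation", "value": 1.25, "lr": 0.0, "p_value": 0.0, "n_left": 34, "n_right": 979, "feasible": true, "lr_select": 0.0, "lr_confirm": 0.0, "p_confirm": 0.0},
  "left": {"n": 34, "depth": 1, "fit": null, "label": 1},
  "right": {
   "n": 979, "depth": 1, "fit": null,
   "split": {"covariate": "overvaluation", "value": 3.75, "lr": 0.0, "p_value": 0.0, "n_left": 109, "n_right": 870, "feasible": true, "lr_select": 0.0, "lr_confirm": 0.0, "p_confirm": 0.0},
   "left": {"n": 109, "depth": 2, "fit": null, "label": 2},
   "right": {
    "n": 870, "depth": 2, "fit": null,
    "split": {"covariate": "overvaluation", "value": 4.75, "lr": 0.0, "p_value": 0.0, "n_left": 111, "n_right": 759, "feasible": true, "lr_select": 0.0, "lr_confirm": 0.0, "p_confirm": 0.0},
    "left": {"n": 111, "depth": 3, "fit": null, "label": 3},
    "right": {
     "n": 759, "depth": 3, "fit": null,
     "split": {"covariate": "overvaluation", "value": 5.75, "lr": 0.0, "p_value": 0.0, "n_left": 177, "n_right": 582, "feasible": true, "lr_select": 0.0, "lr_confirm": 0.0, "p_confirm": 0.0},
     "left": {"n": 177, "depth": 4, "fit": null, "label": 4},
     "right": {"n": 582, "depth": 4, "fit": null, "label": 5}
    }
   }
  }
 }
}
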