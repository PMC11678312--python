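"""combatcv: ComBat harmonization inside leakage-safe cross-validation.

Multi-scanner MRI morphometry carries batch effects that confound disease
classification.  This package provides an empirical-Bayes location-scale
harmonizer (ComBat) with explicit fit-split strategies, training-fold-only
class balancing, a nested evaluation pipeline, and a synthetic cohort
generator -- built to demonstrate that fitting harmonization with the
diagnostic group as a covariate leaks labels and inflates AUC, while
leakage-safe harmonization does not.
"""

__version__ = "0.1.0"

from .cohort import (CohortConfig, FeatureTable, ScannerSpec,
                     benefit_demo_config, default_cohort_config,
                     filter_eligible_scanners, generate_cohort,
                     leakage_demo_config, prepare_features, summarize_cohort)
from .combat import (CombatModel, CovariateDesign, HarmonizationStrategy,
                     apply_combat, fit_combat, harmonize_splits)
from .metrics import (EvaluationReport, LeakageReport, balanced_accuracy,
                      leakage_comparison, roc_auc, scanner_specific_report)
from .pipeline import (SearchSpace, SplitPlan, TrialResult, make_cv_folds,
                       random_search, run_multi_scanner, run_single_scanner,
                       stratified_holdout, train_classifier)
from .resampling import (BalanceConfig, balance_training_set, flip_augment,
                         random_undersample, smote)

__all__ = [name for name in dir() if not name.startswith("_")]
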