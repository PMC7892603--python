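# CIE 1924 photopic luminous efficiency V(lambda), peak 1 at 555 nm
# interpolated to 1 nm (PCHIP) from the standard 5-10 nm tabulation
# wavelength_nm,value
380,3.9e-05
381,4.01408e-05
382,4.34162e-05
383,4.86056e-05
384,5.54886e-05
385,6.38445e-05
386,7.34529e-05
387,8.40932e-05
388,9.55448e-05
389,0.000107587
390,0.00012
391,0.000134163
392,0.000151544
393,0.000172056
394,0.000195613
395,0.000222127
396,0.000251511
397,0.000283677
398,0.000318539
399,0.000356009
400,0.000396
401,0.00044084
402,0.000493092
403,0.000553023
404,0.0006209
405,0.000696991
406,0.000781563
407,0.000874882
408,0.000977217
409,0.00108883
410,0.00121
411,0.00135347
412,0.00153087
413,0.00174076
414,0.00198173
415,0.00225234
416,0.00255116
417,0.00287676
418,0.00322772
419,0.00360261
420,0.004
421,0.00446133
422,0.00502101
423,0.00566704
424,0.00638743
425,0.0071702
426,0.00800336
427,0.0088749
428,0.00977285
429,0.0106852
430,0.0116
431,0.0125413
432,0.0135384
433,0.0145869
434,0.0156824
435,0.0168207
436,0.0179973
437,0.0192078
438,0.0204481
439,0.0217136
440,0.023
441,0.0243088
442,0.0256474
443,0.0270205
444,0.028433
445,0.0298896
446,0.031395
447,0.032954
448,0.0345713
449,0.0362517
450,0.038
451,0.0398293
452,0.0417479
453,0.0437532
454,0.0458427
455,0.0480136
456,0.0502635
457,0.0525896
458,0.0549895
459,0.0574605
460,0.06
461,0.0626125
462,0.0653098
463,0.0681007
464,0.0709938
465,0.0739976
466,0.0771208
467,0.080372
468,0.0837598
469,0.087293
470,0.09098
471,0.0948665
472,0.0989851
473,0.103325
474,0.107877
475,0.112628
476,0.117569
477,0.12269
478,0.127979
479,0.133426
480,0.13902
481,0.144764
482,0.150687
483,0.156817
484,0.163185
485,0.16982
486,0.176751
487,0.184007
488,0.191617
489,0.199612
490,0.20802
491,0.216962
492,0.226527
493,0.236693
494,0.247441
495,0.25875
496,0.2706
497,0.28297
498,0.29584
499,0.309191
500,0.323
501,0.337673
502,0.35352
503,0.370376
504,0.388081
505,0.406471
506,0.425383
507,0.444654
508,0.464123
509,0.483626
510,0.503
511,0.522816
512,0.543566
513,0.564975
514,0.586765
515,0.608659
516,0.63038
517,0.651652
518,0.672197
519,0.691739
520,0.71
521,0.727423
522,0.744577
523,0.761378
524,0.777742
525,0.793583
526,0.808818
527,0.823362
528,0.837129
529,0.850037
530,0.862
531,0.87335
532,0.884426
533,0.895151
534,0.905449
535,0.915244
536,0.924459
537,0.933018
538,0.940846
539,0.947865
540,0.954
541,0.959601
542,0.965027
543,0.97022
544,0.975118
545,0.979661
546,0.98379
547,0.987443
548,0.990561
549,0.993084
550,0.99495
551,0.996447
552,0.997821
553,0.998951
554,0.999718
555,1
556,0.999723
557,0.998968
558,0.997853
559,0.996491
560,0.995
561,0.993074
562,0.990391
563,0.987035
564,0.983095
565,0.978655
566,0.973803
567,0.968625
568,0.963208
569,0.957637
570,0.952
571,0.94599
572,0.939292
573,0.931982
574,0.924136
575,0.915827
576,0.907133
577,0.898128
578,0.888887
579,0.879486
580,0.87
581,0.86021
582,0.849896
583,0.839128
584,0.827977
585,0.816514
586,0.80481
587,0.792935
588,0.780962
589,0.76896
590,0.757
591,0.744964
592,0.732709
593,0.72027
594,0.707682
595,0.694981
596,0.682201
597,0.669378
598,0.656546
599,0.643742
600,0.631
601,0.618254
602,0.605431
603,0.592555
604,0.57965
605,0.566742
606,0.553854
607,0.541012
608,0.528239
609,0.51556
610,0.503
611,0.490535
612,0.478127
613,0.465776
614,0.453483
615,0.44125
616,0.429076
617,0.416963
618,0.404913
619,0.392925
620,0.381
621,0.369031
622,0.356957
623,0.344848
624,0.332773
625,0.320804
626,0.309011
627,0.297464
628,0.286232
629,0.275388
630,0.265
631,0.254967
632,0.245145
633,0.235541
634,0.226161
635,0.217014
636,0.208105
637,0.199442
638,0.191032
639,0.182883
640,0.175
641,0.167315
642,0.159768
643,0.152381
644,0.145177
645,0.138176
646,0.131401
647,0.124874
648,0.118617
649,0.112652
650,0.107
651,0.101587
652,0.0963301
653,0.0912382
654,0.0863207
655,0.081587
656,0.0770463
657,0.072708
658,0.0685813
659,0.0646755
660,0.061
661,0.0574845
662,0.0540633
663,0.0507524
664,0.0475676
665,0.0445249
666,0.0416402
667,0.0389295
668,0.0364086
669,0.0340934
670,0.032
671,0.0300782
672,0.0282638
673,0.0265517
674,0.0249368
675,0.023414
676,0.021978
677,0.0206237
678,0.0193461
679,0.0181399
680,0.017
681,0.0159064
682,0.0148462
683,0.0138247
684,0.0128473
685,0.0119193
686,0.0110463
687,0.0102334
688,0.00948616
689,0.0088099
690,0.00821
691,0.00766574
692,0.00715247
693,0.0066697
694,0.00621691
695,0.00579362
696,0.00539932
697,0.0050335
698,0.00469568
699,0.00438535
700,0.004102
701,0.00383935
702,0.00359122
703,0.00335729
704,0.00313725
705,0.00293079
706,0.00273758
707,0.00255731
708,0.00238967
709,0.00223434
710,0.002091
711,0.00195674
712,0.00182891
713,0.00170758
714,0.00159283
715,0.00148475
716,0.0013834
717,0.00128888
718,0.00120125
719,0.0011206
720,0.001047
721,0.000978731
722,0.000913991
723,0.000852755
724,0.000794996
725,0.000740688
726,0.000689806
727,0.000642322
728,0.00059821
729,0.000557445
730,0.00052
731,0.000484992
732,0.000451593
733,0.000419859
734,0.000389845
735,0.000361607
736,0.0003352
737,0.000310681
738,0.000288104
739,0.000267525
740,0.000249
741,0.000231967
742,0.000215831
743,0.000200601
744,0.000186284
745,0.000172889
746,0.000160422
747,0.000148892
748,0.000138306
749,0.000128673
750,0.00012
751,0.000112046
752,0.000104556
753,9.752e-05
754,9.09257e-05
755,8.47619e-05
756,7.90171e-05
757,7.368e-05
758,6.8739e-05
759,6.41829e-05
760,6e-05
761,5.61e-05
762,5.24e-05
763,4.89e-05
764,4.56e-05
765,4.25e-05
766,3.96e-05
767,3.69e-05
768,3.44e-05
769,3.21e-05
770,3e-05
771,2.80275e-05
772,2.612e-05
773,2.42925e-05
774,2.256e-05
775,2.09375e-05
776,1.944e-05
777,1.80825e-05
778,1.688e-05
779,1.58475e-05
780,1.5e-05
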