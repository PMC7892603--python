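# CIE 1951 scotopic luminous efficiency V'(lambda), peak 1 at 507 nm
# interpolated to 1 nm (PCHIP) from the standard 5-10 nm tabulation
# wavelength_nm,value
380,0.000589
381,0.000610629
382,0.000673104
383,0.000772804
384,0.000906111
385,0.00106941
386,0.00125907
387,0.00147148
388,0.00170301
389,0.00195006
390,0.002209
391,0.00252105
392,0.00292809
393,0.0034275
394,0.00401668
395,0.00469299
396,0.00545383
397,0.00629656
398,0.00721858
399,0.00821727
400,0.00929
401,0.0105783
402,0.0122099
403,0.0141616
404,0.0164103
405,0.0189328
406,0.0217059
407,0.0247063
408,0.0279109
409,0.0312965
410,0.03484
411,0.0388017
412,0.043417
413,0.0486254
414,0.0543662
415,0.0605789
416,0.0672029
417,0.0741777
418,0.0814425
419,0.0889368
420,0.0966
421,0.104719
422,0.113564
423,0.123044
424,0.133073
425,0.143561
426,0.15442
427,0.165562
428,0.176898
429,0.18834
430,0.1998
431,0.21151
432,0.223702
433,0.236289
434,0.249184
435,0.262299
436,0.275546
437,0.288837
438,0.302085
439,0.315202
440,0.3281
441,0.340918
442,0.353822
443,0.366771
444,0.37972
445,0.392626
446,0.405447
447,0.418137
448,0.430655
449,0.442957
450,0.455
451,0.466779
452,0.478343
453,0.489723
454,0.500952
455,0.512063
456,0.52309
457,0.534064
458,0.545018
459,0.555986
460,0.567
461,0.577985
462,0.588866
463,0.599674
464,0.610443
465,0.621203
466,0.631986
467,0.642826
468,0.653753
469,0.664801
470,0.676
471,0.687392
472,0.698968
473,0.710685
474,0.722499
475,0.734367
476,0.746246
477,0.758092
478,0.769862
479,0.781512
480,0.793
481,0.804511
482,0.816194
483,0.82795
484,0.839681
485,0.851288
486,0.862671
487,0.873733
488,0.884374
489,0.894496
490,0.904
491,0.913215
492,0.922452
493,0.931584
494,0.940486
495,0.949032
496,0.957095
497,0.964549
498,0.971269
499,0.977128
500,0.982
501,0.986213
502,0.990074
503,0.993429
504,0.996123
505,0.998
506,0.999354
507,1
508,0.999561
509,0.998455
510,0.997
511,0.994773
512,0.991246
513,0.986575
514,0.980917
515,0.974428
516,0.967264
517,0.959584
518,0.951541
519,0.943295
520,0.935
521,0.926093
522,0.916006
523,0.90489
524,0.892897
525,0.880179
526,0.866886
527,0.85317
528,0.839183
529,0.825076
530,0.811
531,0.796628
532,0.7816
533,0.766018
534,0.749985
535,0.733601
536,0.716969
537,0.700191
538,0.683368
539,0.666604
540,0.65
541,0.633352
542,0.616442
543,0.599345
544,0.582141
545,0.564907
546,0.54772
547,0.530659
548,0.5138
549,0.497221
550,0.481
551,0.46498
552,0.448989
553,0.433083
554,0.417317
555,0.401748
556,0.386431
557,0.371422
558,0.356776
559,0.34255
560,0.3288
561,0.315384
562,0.302151
563,0.28914
564,0.276391
565,0.263943
566,0.251835
567,0.240108
568,0.2288
569,0.217951
570,0.2076
571,0.197619
572,0.187869
573,0.178375
574,0.169162
575,0.160256
576,0.151682
577,0.143464
578,0.135627
579,0.128198
580,0.1212
581,0.114522
582,0.108047
583,0.10179
584,0.0957691
585,0.0899994
586,0.0844977
587,0.0792805
588,0.0743642
589,0.0697652
590,0.0655
591,0.0614812
592,0.0576159
593,0.0539118
594,0.0503767
595,0.0470184
596,0.0438446
597,0.040863
598,0.0380816
599,0.035508
600,0.03315
601,0.0309502
602,0.0288481
603,0.0268469
604,0.0249498
605,0.0231599
606,0.0214805
607,0.0199145
608,0.0184654
609,0.0171361
610,0.01593
611,0.0148134
612,0.0137515
613,0.0127456
614,0.0117967
615,0.0109061
616,0.0100751
617,0.00930477
618,0.00859634
619,0.00795102
620,0.00737
621,0.00683549
622,0.00632914
623,0.00585131
624,0.00540234
625,0.00498261
626,0.00459248
627,0.00423229
628,0.0039024
629,0.00360319
630,0.003335
631,0.00308917
632,0.00285687
633,0.00263818
634,0.00243321
635,0.00224206
636,0.00206483
637,0.0019016
638,0.00175249
639,0.00161759
640,0.001497
641,0.00138672
642,0.0012827
643,0.00118494
644,0.00109347
645,0.00100828
646,0.000929388
647,0.000856804
648,0.000790539
649,0.000730601
650,0.000677
651,0.000628001
652,0.000581849
653,0.000538525
654,0.000498011
655,0.000460289
656,0.000425339
657,0.000393144
658,0.000363685
659,0.000336943
660,0.0003129
661,0.000290837
662,0.00027004
663,0.000250498
664,0.000232201
665,0.00021514
666,0.000199303
667,0.000184681
668,0.000171264
669,0.00015904
670,0.000148
671,0.000137834
672,0.000128238
673,0.000119207
674,0.000110737
675,0.000102825
676,9.54675e-05
677,8.86598e-05
678,8.23985e-05
679,7.66798e-05
680,7.15e-05
681,6.67213e-05
682,6.2207e-05
683,5.79548e-05
684,5.39623e-05
685,5.02272e-05
686,4.67472e-05
687,4.35197e-05
688,4.05426e-05
689,3.78135e-05
690,3.533e-05
691,3.30307e-05
692,3.08551e-05
693,2.88025e-05
694,2.68718e-05
695,2.50623e-05
696,2.33729e-05
697,2.18029e-05
698,2.03513e-05
699,1.90173e-05
700,1.78e-05
701,1.66707e-05
702,1.56011e-05
703,1.45907e-05
704,1.36391e-05
705,1.27459e-05
706,1.19106e-05
707,1.11328e-05
708,1.04121e-05
709,9.74794e-06
710,9.14e-06
711,8.57471e-06
712,8.0387e-06
713,7.53177e-06
714,7.0537e-06
715,6.60429e-06
716,6.18334e-06
717,5.79064e-06
718,5.42599e-06
719,5.08918e-06
720,4.78e-06
721,4.49195e-06
722,4.21858e-06
723,3.95976e-06
724,3.7154e-06
725,3.48536e-06
726,3.26953e-06
727,3.06779e-06
728,2.88004e-06
729,2.70615e-06
730,2.546e-06
731,2.39642e-06
732,2.25428e-06
733,2.11952e-06
734,1.9921e-06
735,1.87198e-06
736,1.75909e-06
737,1.6534e-06
738,1.55485e-06
739,1.4634e-06
740,1.379e-06
741,1.30006e-06
742,1.22499e-06
743,1.15377e-06
744,1.08636e-06
745,1.02272e-06
746,9.62832e-07
747,9.06646e-07
748,8.54135e-07
749,8.05265e-07
750,7.6e-07
751,7.17545e-07
752,6.77116e-07
753,6.387e-07
754,6.02282e-07
755,5.67851e-07
756,5.35391e-07
757,5.0489e-07
758,4.76333e-07
759,4.49708e-07
760,4.25e-07
761,4.01789e-07
762,3.7966e-07
763,3.58607e-07
764,3.38627e-07
765,3.19714e-07
766,3.01864e-07
767,2.85072e-07
768,2.69334e-07
769,2.54645e-07
770,2.41e-07
771,2.28062e-07
772,2.15545e-07
773,2.03518e-07
774,1.92053e-07
775,1.81219e-07
776,1.71089e-07
777,1.61731e-07
778,1.53216e-07
779,1.45616e-07
780,1.39e-07
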