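# SYNTHETIC standard-observer crystalline-lens transmittance
# T(lambda) = 10^(-2.0 * exp(-(lambda-380)/50)), dimensionless in [0,1]
# wavelength_nm,value
380,0.01
381,0.0109548
382,0.011979
383,0.0130759
384,0.0142484
385,0.0154998
386,0.0168329
387,0.0182509
388,0.0197566
389,0.021353
390,0.023043
391,0.0248292
392,0.0267143
393,0.028701
394,0.0307916
395,0.0329886
396,0.0352941
397,0.0377102
398,0.040239
399,0.0428822
400,0.0456415
401,0.0485184
402,0.0515142
403,0.0546302
404,0.0578673
405,0.0612264
406,0.0647081
407,0.068313
408,0.0720414
409,0.0758933
410,0.0798687
411,0.0839675
412,0.0881891
413,0.0925331
414,0.0969987
415,0.101585
416,0.106291
417,0.111115
418,0.116056
419,0.121112
420,0.126282
421,0.131564
422,0.136955
423,0.142454
424,0.148059
425,0.153766
426,0.159574
427,0.16548
428,0.17148
429,0.177573
430,0.183756
431,0.190025
432,0.196377
433,0.20281
434,0.209319
435,0.215903
436,0.222557
437,0.229278
438,0.236063
439,0.242908
440,0.249811
441,0.256767
442,0.263774
443,0.270827
444,0.277924
445,0.28506
446,0.292233
447,0.299439
448,0.306675
449,0.313937
450,0.321223
451,0.328528
452,0.335849
453,0.343184
454,0.35053
455,0.357882
456,0.365238
457,0.372596
458,0.379951
459,0.387302
460,0.394645
461,0.401978
462,0.409298
463,0.416603
464,0.423889
465,0.431155
466,0.438397
467,0.445614
468,0.452804
469,0.459964
470,0.467092
471,0.474186
472,0.481244
473,0.488264
474,0.495245
475,0.502184
476,0.50908
477,0.515932
478,0.522737
479,0.529495
480,0.536203
481,0.542862
482,0.549468
483,0.556022
484,0.562522
485,0.568967
486,0.575356
487,0.581688
488,0.587963
489,0.594179
490,0.600335
491,0.606432
492,0.612467
493,0.618442
494,0.624355
495,0.630206
496,0.635994
497,0.641719
498,0.64738
499,0.652978
500,0.658513
501,0.663983
502,0.669389
503,0.67473
504,0.680007
505,0.68522
506,0.690368
507,0.695452
508,0.700472
509,0.705427
510,0.710318
511,0.715145
512,0.719909
513,0.724609
514,0.729245
515,0.733819
516,0.73833
517,0.742778
518,0.747165
519,0.75149
520,0.755753
521,0.759955
522,0.764097
523,0.768179
524,0.772201
525,0.776164
526,0.780068
527,0.783914
528,0.787702
529,0.791433
530,0.795108
531,0.798726
532,0.802288
533,0.805795
534,0.809248
535,0.812646
536,0.815992
537,0.819284
538,0.822524
539,0.825712
540,0.828849
541,0.831936
542,0.834973
543,0.83796
544,0.840898
545,0.843789
546,0.846631
547,0.849427
548,0.852176
549,0.85488
550,0.857538
551,0.860152
552,0.862722
553,0.865248
554,0.867731
555,0.870172
556,0.872572
557,0.87493
558,0.877248
559,0.879526
560,0.881764
561,0.883964
562,0.886126
563,0.88825
564,0.890336
565,0.892386
566,0.894401
567,0.896379
568,0.898323
569,0.900232
570,0.902108
571,0.90395
572,0.905759
573,0.907536
574,0.909281
575,0.910995
576,0.912678
577,0.914331
578,0.915954
579,0.917548
580,0.919113
581,0.920649
582,0.922157
583,0.923638
584,0.925092
585,0.92652
586,0.927921
587,0.929296
588,0.930647
589,0.931972
590,0.933273
591,0.93455
592,0.935804
593,0.937034
594,0.938242
595,0.939427
596,0.94059
597,0.941731
598,0.942851
599,0.943951
600,0.945029
601,0.946088
602,0.947127
603,0.948146
604,0.949146
605,0.950128
606,0.951091
607,0.952036
608,0.952963
609,0.953872
610,0.954765
611,0.95564
612,0.956499
613,0.957342
614,0.958169
615,0.95898
616,0.959775
617,0.960556
618,0.961322
619,0.962073
620,0.96281
621,0.963533
622,0.964242
623,0.964937
624,0.965619
625,0.966289
626,0.966945
627,0.967589
628,0.96822
629,0.96884
630,0.969447
631,0.970043
632,0.970627
633,0.9712
634,0.971763
635,0.972314
636,0.972855
637,0.973385
638,0.973905
639,0.974415
640,0.974915
641,0.975406
642,0.975887
643,0.976359
644,0.976821
645,0.977275
646,0.97772
647,0.978156
648,0.978584
649,0.979004
650,0.979415
651,0.979819
652,0.980214
653,0.980602
654,0.980983
655,0.981356
656,0.981722
657,0.98208
658,0.982432
659,0.982777
660,0.983115
661,0.983446
662,0.983772
663,0.98409
664,0.984403
665,0.984709
666,0.98501
667,0.985304
668,0.985593
669,0.985877
670,0.986154
671,0.986427
672,0.986694
673,0.986955
674,0.987212
675,0.987464
676,0.98771
677,0.987952
678,0.988189
679,0.988422
680,0.98865
681,0.988873
682,0.989092
683,0.989307
684,0.989518
685,0.989724
686,0.989927
687,0.990125
688,0.99032
689,0.990511
690,0.990698
691,0.990881
692,0.991061
693,0.991237
694,0.99141
695,0.991579
696,0.991745
697,0.991908
698,0.992068
699,0.992224
700,0.992377
701,0.992528
702,0.992675
703,0.99282
704,0.992961
705,0.9931
706,0.993236
707,0.99337
708,0.993501
709,0.993629
710,0.993755
711,0.993878
712,0.993999
713,0.994117
714,0.994234
715,0.994347
716,0.994459
717,0.994569
718,0.994676
719,0.994781
720,0.994884
721,0.994985
722,0.995084
723,0.995181
724,0.995276
725,0.99537
726,0.995461
727,0.995551
728,0.995639
729,0.995725
730,0.995809
731,0.995892
732,0.995973
733,0.996053
734,0.996131
735,0.996207
736,0.996282
737,0.996356
738,0.996428
739,0.996499
740,0.996568
741,0.996636
742,0.996702
743,0.996767
744,0.996831
745,0.996894
746,0.996955
747,0.997015
748,0.997074
749,0.997132
750,0.997189
751,0.997245
752,0.997299
753,0.997353
754,0.997405
755,0.997456
756,0.997507
757,0.997556
758,0.997604
759,0.997652
760,0.997698
761,0.997744
762,0.997788
763,0.997832
764,0.997875
765,0.997917
766,0.997958
767,0.997998
768,0.998038
769,0.998077
770,0.998115
771,0.998152
772,0.998189
773,0.998225
774,0.99826
775,0.998294
776,0.998328
777,0.998361
778,0.998393
779,0.998425
780,0.998456
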